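"""Fitted occurrence trajectories, post hoc contrasts and trend summaries.

From a fitted occurrence GLMM this module produces:

* estimated marginal means — the link-scale linear predictor of each
  time-bin x species cell at the random-effect mode zero, with Wald
  95% intervals back-transformed through the inverse logit; guild
  curves average member-species link predictions with equal weight
  before back-transforming;
* Tukey-style all-pairwise bin contrasts per taxon or guild, with the
  family-wise adjusted p evaluated from the max-|z| distribution of a
  multivariate normal with the contrast correlation matrix;
* a trend summary per taxon/guild: overall first-vs-last change,
  earliest significant departure from the Pleistocene baseline, peak
  bin, and earliest significant decline from the peak.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .binning import TimeBin
from .glmm import GLMMFit

__all__ = [
    "MarginalEstimate",
    "TrendSummary",
    "estimated_marginal_means",
    "tukey_contrasts",
    "detect_trend_summary",
]

Z95 = norm.ppf(0.975)


@dataclass
class MarginalEstimate:
    bin: TimeBin
    label: str
    link_estimate: float
    link_se: float
    proportion: float
    ci_low: float
    ci_high: float


def _usable_cells(fit: GLMMFit) -> set:
    """Cells that exist and are not completely separated.

    A separated cell (response constant at 0 or 1) has a divergent
    logit MLE: its Wald inference is meaningless, so the estimate is
    reported as missing and contrasts involving it are skipped.
    """
    return set(fit.design.cells) - set(fit.separated_cells)


def _cell_L(fit: GLMMFit, tb: TimeBin, label: str, guild: bool) -> np.ndarray:
    d = fit.design
    usable = _usable_cells(fit)
    if guild:
        rows = [d.cell_row(tb, sp) for sp in d.species if (tb, sp) in usable]
        if not rows:
            raise KeyError((tb, label))
        return np.mean(rows, axis=0)
    if (tb, label) not in usable:
        raise KeyError((tb, label))
    return d.cell_row(tb, label)


def estimated_marginal_means(
    fit: GLMMFit, *, guild_label: str | None = None
) -> list[MarginalEstimate]:
    """Marginal estimates per bin for each species, plus an optional
    equal-weight guild average across member species.

    Empty and separated bin x species cells are omitted; the guild
    average runs over the estimable member cells of each bin.
    """
    out = []
    d = fit.design
    labels = [(sp, False) for sp in d.species]
    if guild_label is not None and len(d.species) > 1:
        labels.append((guild_label, True))
    cellset = _usable_cells(fit)
    for label, is_guild in labels:
        for tb in d.bins:
            if not is_guild and (tb, label) not in cellset:
                continue
            if is_guild and not any((tb, sp) in cellset for sp in d.species):
                continue
            L = _cell_L(fit, tb, label, is_guild)
            est = float(L @ fit.beta)
            se = float(np.sqrt(max(L @ fit.vcov_beta @ L, 0.0)))
            out.append(
                MarginalEstimate(
                    bin=tb,
                    label=label,
                    link_estimate=est,
                    link_se=se,
                    proportion=float(expit(est)),
                    ci_low=float(expit(est - Z95 * se)),
                    ci_high=float(expit(est + Z95 * se)),
                )
            )
    return out


def estimates_frame(estimates: list[MarginalEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin": [e.bin.name for e in estimates],
            "bin_order": [int(e.bin) for e in estimates],
            "label": [e.label for e in estimates],
            "link_estimate": [e.link_estimate for e in estimates],
            "link_se": [e.link_se for e in estimates],
            "proportion": [e.proportion for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
        }
    )


def _family_seed(label: str, n: int) -> int:
    # deterministic per contrast family, independent of global state
    h = hashlib.sha256(f"tukey:{label}:{n}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def tukey_contrasts(
    fit: GLMMFit,
    label: str,
    *,
    guild: bool = False,
    n_mc: int = 100_000,
) -> pd.DataFrame:
    """All pairwise bin contrasts for one taxon/guild, Tukey-adjusted.

    The family-wise adjusted p for contrast j is
    P(max_k |Z_k| >= |z_j|) with Z multivariate normal under the
    contrast correlation matrix; evaluated by seeded Monte Carlo
    (except for families of a single contrast, which reduce exactly to
    the unadjusted two-sided z-test).
    """
    d = fit.design
    cellset = _usable_cells(fit)
    bins = [
        tb
        for tb in d.bins
        if (guild and any((tb, sp) in cellset for sp in d.species))
        or (not guild and (tb, label) in cellset)
    ]
    if len(bins) < 2:
        raise ValueError(f"{label}: need >= 2 bins with estimates")
    Ls = {tb: _cell_L(fit, tb, label, guild) for tb in bins}
    pairs = [(a, b) for i, a in enumerate(bins) for b in bins[i + 1 :]]
    C = np.array([Ls[b] - Ls[a] for a, b in pairs])
    cov = C @ fit.vcov_beta @ C.T
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    if np.any(se == 0):
        bad = [pairs[i] for i in np.where(se == 0)[0]]
        raise np.linalg.LinAlgError(f"degenerate contrast covariance for pairs {bad}")
    est = C @ fit.beta
    z = est / se
    raw_p = 2 * norm.sf(np.abs(z))
    if len(pairs) == 1:
        adj_p = raw_p.copy()
    else:
        R = cov / np.outer(se, se)
        # nearest-PSD guard for FD noise in vcov
        w, V = np.linalg.eigh(0.5 * (R + R.T))
        w = np.clip(w, 1e-10, None)
        A = V * np.sqrt(w)
        rng = np.random.default_rng(_family_seed(label, len(pairs)))
        draws = rng.standard_normal((n_mc, len(w))) @ A.T
        maxabs = np.abs(draws).max(axis=1)
        maxabs.sort()
        exceed = len(maxabs) - np.searchsorted(maxabs, np.abs(z), side="left")
        adj_p = (1.0 + exceed) / (n_mc + 1.0)
        adj_p = np.maximum(adj_p, raw_p)
    return pd.DataFrame(
        {
            "label": label,
            "bin_a": [a.name for a, _ in pairs],
            "bin_b": [b.name for _, b in pairs],
            "estimate": est,
            "se": se,
            "z": z,
            "raw_p": raw_p,
            "adj_p": adj_p,
        }
    )


@dataclass
class TrendSummary:
    label: str
    start_proportion: float
    end_proportion: float
    overall_significant: bool
    earliest_sig_change_vs_pleistocene: TimeBin | None
    peak_bin: TimeBin
    earliest_sig_decline_from_peak: TimeBin | None


def detect_trend_summary(
    estimates: list[MarginalEstimate],
    contrasts: pd.DataFrame,
    label: str,
    alpha: float = 0.05,
) -> TrendSummary:
    """Trend-table row for one taxon/guild.

    Uses the Tukey-adjusted contrast p-values: overall change is the
    first-vs-last bin contrast; the baseline column reports the
    earliest bin significantly different from the Pleistocene; the
    decline column reports the earliest post-peak bin significantly
    below the peak.
    """
    ests = sorted((e for e in estimates if e.label == label), key=lambda e: int(e.bin))
    if not ests:
        raise ValueError(f"no estimates for {label}")
    sub = contrasts[contrasts["label"] == label]

    def contrast_p(a: TimeBin, b: TimeBin) -> float | None:
        lo, hi = (a, b) if a <= b else (b, a)
        row = sub[(sub["bin_a"] == lo.name) & (sub["bin_b"] == hi.name)]
        return None if row.empty else float(row["adj_p"].iloc[0])

    first, last = ests[0], ests[-1]
    p_overall = contrast_p(first.bin, last.bin)
    overall_sig = p_overall is not None and p_overall < alpha

    earliest_change = None
    if first.bin is TimeBin.PLEISTOCENE:
        for e in ests[1:]:
            p = contrast_p(TimeBin.PLEISTOCENE, e.bin)
            if p is not None and p < alpha:
                earliest_change = e.bin
                break

    peak = max(ests, key=lambda e: e.proportion)
    earliest_decline = None
    for e in ests:
        if e.bin <= peak.bin or e.proportion >= peak.proportion:
            continue
        p = contrast_p(peak.bin, e.bin)
        if p is not None and p < alpha:
            earliest_decline = e.bin
            break

    return TrendSummary(
        label=label,
        start_proportion=first.proportion,
        end_proportion=last.proportion,
        overall_significant=overall_sig,
        earliest_sig_change_vs_pleistocene=earliest_change,
        peak_bin=peak.bin,
        earliest_sig_decline_from_peak=earliest_decline,
    )


def trend_table(summaries: list[TrendSummary]) -> pd.DataFrame:
    """Publication-style trend table (occurrence as whole percent)."""
    return pd.DataFrame(
        {
            "label": [s.label for s in summaries],
            "start_pct": [round(100 * s.start_proportion) for s in summaries],
            "end_pct": [round(100 * s.end_proportion) for s in summaries],
            "overall_significant": [s.overall_significant for s in summaries],
            "earliest_sig_change_vs_pleistocene": [
                s.earliest_sig_change_vs_pleistocene.name
                if s.earliest_sig_change_vs_pleistocene
                else ""
                for s in summaries
            ],
            "peak_bin": [s.peak_bin.name for s in summaries],
            "earliest_sig_decline_from_peak": [
                s.earliest_sig_decline_from_peak.name if s.earliest_sig_decline_from_peak else ""
                for s in summaries
            ],
        }
    )
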