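"""End-to-end orchestration: ingest -> guild models -> diagnostics -> dissimilarity.

A single :class:`RunConfig` drives the full reconstruction: curate the
survey records into per-bin matrices, fit one occurrence GLMM per
life-history guild (species x bin interaction, country random
intercept), derive marginal trajectories, Tukey contrasts and trend
summaries, run residual diagnostics, and compute the within-country
dissimilarity series.  All randomness flows from the single master
seed recorded in the run report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .binning import ReefZone, TimeBin
from .diagnostics import diagnose
from .dissimilarity import compute_series
from .glmm import build_design, fit_binomial_glmm
from .ingest import read_survey_csv, write_matrix_csv
from .life_history import ANALYZED_GUILDS, guild_members
from .records import BinnedOccurrenceMatrix, filter_full_complement, harmonize_records
from .synthetic import default_caribbean_scenario, generate_dataset
from .taxa import ALL_SPECIES
from .trends import (
    detect_trend_summary,
    estimated_marginal_means,
    estimates_frame,
    trend_table,
    tukey_contrasts,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    output_dir: str | Path = "reefchrono_out"
    input_csv: str | None = None  # None -> default synthetic scenario
    input_layout: str = "long"
    zone: ReefZone = ReefZone.CREST
    millepora_included: bool = True
    n_nodes: int = 1
    n_sim: int = 1000
    bootstrap: int = 1000
    permutations: int = 1000
    seed: int = 0
    alpha: float = 0.05
    guild_mode: str = "average"  # "average" (equal-weight emmeans) or "presence"
    ci_quantiles: tuple[float, float] = (5.0, 95.0)
    write_outputs: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("n_sim", "bootstrap", "permutations", "n_nodes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.guild_mode not in ("average", "presence"):
            raise ValueError("guild_mode must be 'average' or 'presence'")


def _zone_matrices(config: RunConfig) -> tuple[dict[TimeBin, BinnedOccurrenceMatrix], dict]:
    if config.input_csv:
        records = read_survey_csv(config.input_csv, layout=config.input_layout)
    else:
        scenario = default_caribbean_scenario(seed=config.seed, zone=config.zone.value)
        records, _truth = generate_dataset(scenario)
    matrices, log = harmonize_records(records)
    return {tb: m for (zone, tb), m in matrices.items() if zone is config.zone}, log


def run_pipeline(config: RunConfig) -> dict:
    """Run everything; write outputs; return the run report."""
    outdir = Path(config.output_dir)
    if config.write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    matrices, curation_log = _zone_matrices(config)
    if not matrices:
        raise ValueError(f"no surveys for zone {config.zone.value}")

    report: dict = {
        "seed": config.seed,
        "zone": config.zone.value,
        "millepora_included": config.millepora_included,
        "n_quadrature_nodes": config.n_nodes,
        "guilds": {},
        "all_converged": True,
    }

    all_estimates, all_contrasts, summaries, gof = [], [], [], {}
    for guild in ANALYZED_GUILDS:
        members = list(guild_members(guild, millepora_included=config.millepora_included))
        filtered = {
            tb: filter_full_complement(m, members)
            for tb, m in matrices.items()
        }
        filtered = {tb: m for tb, m in filtered.items() if m.n_surveys > 0}
        if not filtered:
            report["guilds"][guild.value] = {"skipped": "no complete surveys"}
            continue
        design = build_design(filtered, members, level="species")
        fit = fit_binomial_glmm(design, n_nodes=config.n_nodes)
        report["all_converged"] &= fit.converged
        ests = estimated_marginal_means(fit, guild_label=guild.value)
        all_estimates.extend(ests)
        labels = list(design.species) + ([guild.value] if len(design.species) > 1 else [])
        for label in labels:
            ctr = tukey_contrasts(fit, label, guild=(label == guild.value))
            all_contrasts.append(ctr)
            summaries.append(detect_trend_summary(ests, ctr, label, alpha=config.alpha))
        if config.guild_mode == "presence" and len(members) > 1:
            gdesign = build_design(filtered, members, level="guild", guild_label=guild.value)
            gfit = fit_binomial_glmm(gdesign, n_nodes=config.n_nodes)
            report["all_converged"] &= gfit.converged
            gests = estimated_marginal_means(gfit)
            all_estimates.extend(
                type(e)(**{**e.__dict__, "label": f"{guild.value}_presence"}) for e in gests
            )
        _res, gof_report, qq = diagnose(fit, n_sim=config.n_sim, seed=config.seed + 17)
        gof[guild.value] = gof_report.to_dict()
        report["guilds"][guild.value] = {
            "n_rows": len(design.table),
            "n_countries": design.n_groups,
            "sigma_u": fit.sigma_u,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "separated_cells": [(tb.name, sp) for tb, sp in fit.separated_cells],
        }
        if config.write_outputs:
            qq.to_csv(outdir / f"residuals_{guild.value}.csv", index=False)

    # dissimilarity on the full 14-group complement
    full = {
        tb: filter_full_complement(m, list(ALL_SPECIES)) for tb, m in matrices.items()
    }
    full = {tb: m for tb, m in full.items() if m.n_surveys > 0}
    series = compute_series(
        full,
        config.zone,
        B=config.bootstrap,
        seed=config.seed + 23,
        quantiles=config.ci_quantiles,
        permutations=config.permutations,
    )

    est_df = estimates_frame(all_estimates)
    ctr_df = pd.concat(all_contrasts, ignore_index=True) if all_contrasts else pd.DataFrame()
    trend_df = trend_table(summaries)

    report["curation_log"] = curation_log
    report["dissimilarity_bins"] = len(series.table)
    report["gof"] = gof

    if config.write_outputs:
        for tb, m in sorted(matrices.items()):
            write_matrix_csv(m, outdir / f"matrix_{config.zone.value}_{tb.name}.csv")
        est_df.to_csv(outdir / "marginal_estimates.csv", index=False)
        ctr_df.to_csv(outdir / "contrasts.csv", index=False)
        trend_df.to_csv(outdir / "trend_summary.csv", index=False)
        series.table.to_csv(outdir / "dissimilarity_series.csv", index=False)
        if series.comparisons is not None:
            series.comparisons.to_csv(outdir / "dissimilarity_comparisons.csv", index=False)
        with open(outdir / "gof_reports.json", "w", encoding="utf-8") as fh:
            json.dump(gof, fh, indent=2)
        with open(outdir / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, default=str)

    report["_estimates"] = est_df
    report["_contrasts"] = ctr_df
    report["_trends"] = trend_df
    report["_dissimilarity"] = series
    return report
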