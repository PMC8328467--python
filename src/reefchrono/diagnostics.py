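"""Simulation-based scaled-residual diagnostics for fitted models.

Residuals are put on a standardized [0, 1] scale by simulating many
complete response vectors from the fitted model (re-drawing country
intercepts each simulation) and locating each observed value within
its simulated distribution — the randomized-quantile construction
required for discrete responses, where ties between observed and
simulated values are universal and are broken by uniform jitter from a
dedicated, logged RNG stream.  Under a correctly specified model the
residuals are Uniform(0, 1).

Three pooled goodness-of-fit tests follow: Kolmogorov-Smirnov
uniformity, a simulated two-sided dispersion test on the variance
ratio of observed vs. simulated deviations, and a binomial outlier
test on residuals pinned at exactly 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import binomtest, kstest

from .glmm import GLMMFit

__all__ = [
    "ResidualSet",
    "GofReport",
    "simulate_from_fit",
    "scaled_residuals",
    "gof_tests",
    "diagnose",
]


@dataclass
class ResidualSet:
    scaled_residuals: np.ndarray
    n_simulations: int
    seed: int


@dataclass
class GofReport:
    uniformity_p: float
    dispersion_ratio: float
    dispersion_p: float
    outlier_count: int
    outlier_p: float
    n_rows: int
    n_simulations: int

    def to_dict(self) -> dict:
        return {
            "uniformity_p": self.uniformity_p,
            "dispersion_ratio": self.dispersion_ratio,
            "dispersion_p": self.dispersion_p,
            "outlier_count": self.outlier_count,
            "outlier_p": self.outlier_p,
            "n_rows": self.n_rows,
            "n_simulations": self.n_simulations,
        }


def simulate_from_fit(fit: GLMMFit, n_sim: int = 1000, seed: int = 0) -> np.ndarray:
    """Draw ``n_sim`` complete response vectors from the fitted model.

    Country intercepts are re-drawn Normal(0, sigma_u^2) for every
    simulation, so the simulations carry the full marginal variability
    of the model.  Returns an (n_rows, n_sim) matrix aligned with the
    design's response rows (one per survey x species).
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    if not fit.converged:
        raise ValueError("refusing to simulate from an unconverged fit")
    d = fit.design
    rng = np.random.default_rng(seed)
    eta0 = d.X @ fit.beta
    trials = d.table["trials"].to_numpy(np.int64)
    u = rng.normal(0.0, fit.sigma_u, size=(d.n_groups, n_sim))
    p = expit(eta0[:, None] + u[d.group_idx, :])
    return rng.binomial(trials[:, None], p).astype(np.int32)


def design_rows(fit: GLMMFit) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed successes, trials and fitted means on design rows."""
    d = fit.design
    n = d.table["trials"].to_numpy(np.int64)
    y = d.table["successes"].to_numpy(np.int64)
    mu = expit(d.X @ fit.beta) * n
    return y, n, mu


def scaled_residuals(observed: np.ndarray, simulations: np.ndarray, seed: int = 0) -> ResidualSet:
    """Randomized empirical quantile of each observation among its sims.

    residual = (#{sim < obs} + U * #{sim == obs}) / n_sim with
    U ~ Uniform(0,1): exactly 0/1 when the observation falls strictly
    below/above every simulation, uniformly jittered across ties.
    """
    observed = np.asarray(observed)
    if simulations.shape[0] != observed.shape[0]:
        raise ValueError("simulation rows must match observed length")
    n_sim = simulations.shape[1]
    below = (simulations < observed[:, None]).sum(axis=1)
    ties = (simulations == observed[:, None]).sum(axis=1)
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=observed.shape[0])
    res = (below + u * ties) / n_sim
    return ResidualSet(scaled_residuals=res, n_simulations=n_sim, seed=seed)


def gof_tests(
    residuals: ResidualSet, simulations: np.ndarray, observed: np.ndarray, expected: np.ndarray
) -> GofReport:
    """Uniformity, dispersion and outlier tests on pooled residuals."""
    r = residuals.scaled_residuals
    n_sim = residuals.n_simulations
    uniformity_p = float(kstest(r, "uniform").pvalue)

    var_obs = float(np.var(observed - expected))
    var_sim = np.var(simulations - expected[:, None], axis=0)
    ratio = var_obs / float(np.mean(var_sim))
    p_hi = (1 + np.sum(var_sim >= var_obs)) / (n_sim + 1)
    p_lo = (1 + np.sum(var_sim <= var_obs)) / (n_sim + 1)
    dispersion_p = float(min(1.0, 2 * min(p_hi, p_lo)))

    n_extreme = int(np.sum((r == 0.0) | (r == 1.0)))
    p_row = 2.0 / (n_sim + 1)
    outlier_p = float(binomtest(n_extreme, len(r), p_row).pvalue)

    return GofReport(
        uniformity_p=uniformity_p,
        dispersion_ratio=float(ratio),
        dispersion_p=dispersion_p,
        outlier_count=n_extreme,
        outlier_p=outlier_p,
        n_rows=len(r),
        n_simulations=n_sim,
    )


def diagnose(fit: GLMMFit, n_sim: int = 1000, seed: int = 0) -> tuple[ResidualSet, GofReport, pd.DataFrame]:
    """Full diagnostic pass: simulate, scale residuals, run GOF tests.

    Also returns plot-ready data: per-row scaled residual, fitted
    proportion, and uniform QQ positions.
    """
    sims = simulate_from_fit(fit, n_sim=n_sim, seed=seed)
    y, n, mu = design_rows(fit)
    res = scaled_residuals(y, sims, seed=seed + 1)
    report = gof_tests(res, sims, y, mu)
    order = np.argsort(res.scaled_residuals)
    qq = pd.DataFrame(
        {
            "predicted": mu / np.maximum(n, 1),
            "scaled_residual": res.scaled_residuals,
            "qq_theoretical": np.empty(len(order)),
        }
    )
    qq.loc[qq.index[order], "qq_theoretical"] = (np.arange(len(order)) + 0.5) / len(order)
    return res, report, qq
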