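"""Binomial GLMM with a single random intercept, fit by maximum likelihood.

The occurrence model: for response row *i* (one survey x species cell,
or an aggregated binomial count) in country *g*,

    y_i | u_g ~ Binomial(n_i, logit^{-1}(x_i' beta + u_g)),
    u_g ~ Normal(0, sigma_u^2),

with fixed effects for time bin, species group and their interaction
(treatment coding, Pleistocene and the first species as reference
levels).  The marginal likelihood integrates the country intercept out
by the Laplace approximation (1 quadrature node, the default, matching
the standard GLMM toolchain) or adaptive Gauss-Hermite quadrature for
``n_nodes > 1``.

Log-likelihoods are reported in Bernoulli form (binomial coefficients
omitted), so internally aggregating rows that share a design row and
country — a pure speed optimization — leaves the value unchanged.

The optimizer is quasi-Newton (L-BFGS-B) on (beta, log sigma_u) with an
analytic gradient of the Laplace objective; the inner mode-finding per
country is a damped Newton iteration on a scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp
from numpy.polynomial.hermite_e import hermegauss
import statsmodels.api as sm
from statsmodels.tools import numdiff

from .binning import TimeBin
from .records import BinnedOccurrenceMatrix
from .taxa import SpeciesGroup

__all__ = [
    "GLMMDesign",
    "GLMMFit",
    "build_design",
    "fit_binomial_glmm",
    "fixed_parameter_fit",
    "marginal_loglik",
    "brute_force_loglik",
]


@dataclass
class GLMMDesign:
    """Design for one occurrence model.

    ``table`` is the long response table (one row per survey x species,
    or per survey for guild-level fits) with columns
    ``successes, trials, bin, species, country``.  ``X`` is the fixed
    effect design matrix (treatment coding with interaction), built
    over the non-empty bin x species cells.
    """

    table: pd.DataFrame
    X: np.ndarray
    colnames: list[str]
    group_labels: list[str]
    group_idx: np.ndarray
    bins: list[TimeBin]
    species: list[str]
    cells: list[tuple[TimeBin, str]]
    dropped_cells: list[tuple[TimeBin, str]]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def cell_row(self, tb: TimeBin, sp: str) -> np.ndarray:
        """Design row (L-vector) for the linear predictor of one cell."""
        x = np.zeros(len(self.colnames))
        x[0] = 1.0
        for j, name in enumerate(self.colnames):
            if name == f"bin[{tb.name}]":
                x[j] = 1.0
            elif name == f"species[{sp}]":
                x[j] = 1.0
            elif name == f"bin[{tb.name}]:species[{sp}]":
                x[j] = 1.0
        return x


def build_design(
    matrices: dict[TimeBin, BinnedOccurrenceMatrix],
    members: list[SpeciesGroup],
    *,
    level: str = "species",
    guild_label: str = "guild",
) -> GLMMDesign:
    """Assemble the long response table and fixed-effect design matrix.

    Parameters
    ----------
    matrices
        Full-complement matrices per time bin for one reef zone
        (already passed through ``filter_full_complement``).
    members
        Species groups entering the model.
    level
        ``"species"`` -> one Bernoulli row per survey x member with a
        bin x species interaction design.  ``"guild"`` -> one row per
        survey scoring presence of *any* member (the guild-presence
        parameterization), with bin main effects only.
    """
    rows = []
    for tb in sorted(matrices):
        m = matrices[tb]
        if m.n_surveys == 0:
            continue
        cols = [sp.value for sp in members]
        sub = m.data[cols]
        if sub.isna().any().any():
            raise ValueError(
                f"bin {tb.name}: matrix has missing cells; apply filter_full_complement first"
            )
        if level == "species":
            for sp in cols:
                for sid, val in sub[sp].items():
                    rows.append((sid, m.country.loc[sid], tb, sp, int(val), 1))
        elif level == "guild":
            pres = (sub.sum(axis=1) > 0).astype(int)
            for sid, val in pres.items():
                rows.append((sid, m.country.loc[sid], tb, guild_label, int(val), 1))
        else:
            raise ValueError(f"unknown level {level!r}")
    if not rows:
        raise ValueError("no data rows; all bins empty")
    table = pd.DataFrame(
        rows, columns=["survey_id", "country", "bin", "species", "successes", "trials"]
    )
    return _design_from_table(table)


def _design_from_table(table: pd.DataFrame) -> GLMMDesign:
    bins = sorted(TimeBin(b) for b in table["bin"].unique())
    species = sorted(table["species"].unique())

    present = {(TimeBin(b), s) for b, s in zip(table["bin"], table["species"])}
    cells = [(b, s) for b in bins for s in species if (b, s) in present]
    dropped = [(b, s) for b in bins for s in species if (b, s) not in present]

    n = len(table)
    cols: list[tuple[str, np.ndarray]] = [("Intercept", np.ones(n))]
    b_arr = table["bin"].astype(int).to_numpy()
    s_arr = table["species"].to_numpy()
    for b in bins[1:]:
        cols.append((f"bin[{b.name}]", (b_arr == b).astype(float)))
    for s in species[1:]:
        cols.append((f"species[{s}]", (s_arr == s).astype(float)))
    for b in bins[1:]:
        for s in species[1:]:
            if (b, s) in present:
                cols.append(
                    (f"bin[{b.name}]:species[{s}]", ((b_arr == b) & (s_arr == s)).astype(float))
                )
    X = np.column_stack([c for _, c in cols])
    names = [nm for nm, _ in cols]

    groups = sorted(table["country"].unique())
    gidx = pd.Categorical(table["country"], categories=groups).codes.astype(np.int64)
    return GLMMDesign(
        table=table,
        X=X,
        colnames=names,
        group_labels=list(groups),
        group_idx=gidx,
        bins=list(bins),
        species=list(species),
        cells=cells,
        dropped_cells=dropped,
    )


@dataclass
class GLMMFit:
    """Maximum-likelihood fit of the random-intercept binomial model."""

    design: GLMMDesign
    beta: np.ndarray
    sigma_u: float
    vcov_beta: np.ndarray
    loglik: float
    converged: bool
    n_quadrature_nodes: int
    n_iter: int
    grad_max: float
    u_modes: np.ndarray = field(repr=False)
    separated_cells: list[tuple[TimeBin, str]] = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.design.colnames)


# ---------------------------------------------------------------------------
# likelihood machinery


def _aggregate(design: GLMMDesign):
    """Collapse rows sharing (country, design row) into binomial counts."""
    tab = design.table
    key = pd.MultiIndex.from_arrays(
        [tab["country"].to_numpy(), tab["bin"].to_numpy(), tab["species"].to_numpy()]
    )
    codes, uniques = pd.factorize(key)
    k = len(uniques)
    y = np.bincount(codes, weights=tab["successes"].to_numpy(float), minlength=k)
    n = np.bincount(codes, weights=tab["trials"].to_numpy(float), minlength=k)
    first = np.zeros(k, dtype=np.int64)
    seen = np.zeros(k, dtype=bool)
    for i, c in enumerate(codes):
        if not seen[c]:
            first[c] = i
            seen[c] = True
    X = design.X[first]
    g = design.group_idx[first]
    return X, y, n, g


def _inner_modes(eta0, y, n, gidx, n_groups, s2, u0=None, tol=1e-11, max_iter=100):
    """Damped Newton for the per-group posterior modes of u."""
    u = np.zeros(n_groups) if u0 is None else u0.copy()
    sumy = np.bincount(gidx, weights=y, minlength=n_groups)
    for _ in range(max_iter):
        p = expit(eta0 + u[gidx])
        grad = sumy - np.bincount(gidx, weights=n * p, minlength=n_groups) - u / s2
        W = np.bincount(gidx, weights=n * p * (1 - p), minlength=n_groups)
        step = grad / (W + 1.0 / s2)
        # step halving against divergence on the joint density
        scale = 1.0
        h0 = _joint_by_group(eta0, y, n, gidx, n_groups, u, s2)
        for _ in range(20):
            u_new = u + scale * step
            h1 = _joint_by_group(eta0, y, n, gidx, n_groups, u_new, s2)
            if np.all(h1 >= h0 - 1e-12):
                break
            scale *= 0.5
        u = u + scale * step
        if np.max(np.abs(grad)) < tol * (1 + np.max(np.abs(sumy))):
            break
    return u


def _joint_by_group(eta0, y, n, gidx, n_groups, u, s2):
    """Per-group joint log density (Bernoulli form, prior included, up to const)."""
    eta = eta0 + u[gidx]
    ll = y * eta - n * np.logaddexp(0.0, eta)
    return np.bincount(gidx, weights=ll, minlength=n_groups) - u**2 / (2 * s2)


def marginal_loglik(
    beta, log_sigma, X, y, n, gidx, n_groups, n_nodes=1, u0=None, return_parts=False
):
    """Marginal log-likelihood via Laplace (n_nodes=1) or AGQ."""
    s2 = np.exp(2.0 * log_sigma)
    eta0 = X @ beta
    u = _inner_modes(eta0, y, n, gidx, n_groups, s2, u0=u0)
    p = expit(eta0 + u[gidx])
    W = np.bincount(gidx, weights=n * p * (1 - p), minlength=n_groups)
    h_mode = _joint_by_group(eta0, y, n, gidx, n_groups, u, s2)
    if n_nodes <= 1:
        ll_g = h_mode - 0.5 * np.log1p(s2 * W)
    else:
        # adaptive GH centered at the mode, scaled by the conditional sd
        z, w = hermegauss(n_nodes)  # weights for exp(-z^2/2)
        shat = 1.0 / np.sqrt(W + 1.0 / s2)
        u_nodes = u[:, None] + shat[:, None] * z[None, :]  # (G, K)
        eta = eta0[:, None] + u_nodes[gidx]
        llrows = y[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)
        h = np.empty((n_groups, n_nodes))
        for k in range(n_nodes):
            h[:, k] = np.bincount(gidx, weights=llrows[:, k], minlength=n_groups)
        h -= u_nodes**2 / (2 * s2)
        # int e^{h(u)} du = sum_k w_k shat e^{h(u_k) + z_k^2/2} / sqrt(2 pi sigma^2)
        ll_g = (
            logsumexp(h + 0.5 * z[None, :] ** 2 + np.log(w)[None, :], axis=1)
            + np.log(shat)
            - 0.5 * np.log(2 * np.pi)
            - 0.5 * np.log(s2)
        )
    ll = float(np.sum(ll_g))
    if return_parts:
        return ll, u, W, p
    return ll


def _laplace_neg_loglik_grad(theta, X, y, n, gidx, n_groups, state):
    """Negative Laplace log-likelihood and its analytic gradient.

    Gradient terms use the envelope identity at the inner mode: the
    direct data term contributes sum (y - n p) x; the log-determinant
    correction needs the implicit derivative of the mode.
    """
    beta, log_sigma = theta[:-1], theta[-1]
    s2 = np.exp(2.0 * log_sigma)
    eta0 = X @ beta
    u = _inner_modes(eta0, y, n, gidx, n_groups, s2, u0=state.get("u"))
    state["u"] = u
    p = expit(eta0 + u[gidx])
    w_row = n * p * (1 - p)
    W = np.bincount(gidx, weights=w_row, minlength=n_groups)
    h_mode = _joint_by_group(eta0, y, n, gidx, n_groups, u, s2)
    ll = float(np.sum(h_mode - 0.5 * np.log1p(s2 * W)))

    denom = W + 1.0 / s2  # -d2h/du2 at mode
    resid = y - n * p
    # dl/dbeta: envelope term
    g_beta = X.T @ resid
    # log-det correction: dW/dbeta_j = sum w(1-2p)(x_j + du/dbeta_j)
    wp = w_row * (1 - 2 * p)
    Wp = np.bincount(gidx, weights=wp, minlength=n_groups)  # dW/du per group
    V = np.empty((n_groups, X.shape[1]))
    for j in range(X.shape[1]):
        V[:, j] = np.bincount(gidx, weights=w_row * X[:, j], minlength=n_groups)
    du_dbeta = -V / denom[:, None]
    WpX = np.empty_like(V)
    for j in range(X.shape[1]):
        WpX[:, j] = np.bincount(gidx, weights=wp * X[:, j], minlength=n_groups)
    dW_dbeta = WpX + Wp[:, None] * du_dbeta
    coef = 0.5 * s2 / (1.0 + s2 * W)
    g_beta -= dW_dbeta.T @ coef

    # tau = log sigma: explicit prior term + log-det correction
    du_dtau = 2 * u / (s2 * denom)
    dW_dtau = Wp * du_dtau
    g_tau = float(np.sum(u**2) / s2 - np.sum((2 * s2 * W + s2 * dW_dtau) * 0.5 / (1.0 + s2 * W)))

    grad = np.concatenate([g_beta, [g_tau]])
    return -ll, -grad


def _detect_separation(design: GLMMDesign):
    """Cells where the response is constant (all 0 or all 1)."""
    tab = design.table
    out = []
    for (b, s), sub in tab.groupby(["bin", "species"], sort=False, observed=True):
        tot, tr = sub["successes"].sum(), sub["trials"].sum()
        if tot == 0 or tot == tr:
            out.append((TimeBin(b), s))
    return out


def fit_binomial_glmm(design: GLMMDesign, n_nodes: int = 1, max_iter: int = 500) -> GLMMFit:
    """Fit the model by quasi-Newton maximization of the marginal likelihood.

    ``n_nodes = 1`` is the Laplace approximation (default); higher
    orders use adaptive Gauss-Hermite quadrature.  Wald covariance is
    the inverse observed information (numerical Hessian at the
    optimum), with the random-effect scale profiled jointly.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    X, y, n, gidx = _aggregate(design)
    n_groups = design.n_groups

    # starting values from the fixed-effects GLM
    glm = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial())
    try:
        beta0 = glm.fit(maxiter=100).params
    except Exception:
        beta0 = np.zeros(X.shape[1])
    theta0 = np.concatenate([beta0, [np.log(0.5)]])

    state: dict = {}
    if n_nodes == 1:
        fun = lambda th: _laplace_neg_loglik_grad(th, X, y, n, gidx, n_groups, state)
        jac = True
    else:
        fun = lambda th: -marginal_loglik(
            th[:-1], th[-1], X, y, n, gidx, n_groups, n_nodes, u0=state.get("u")
        )
        jac = None
    bounds = [(None, None)] * X.shape[1] + [(-8.0, 4.0)]
    res = optimize.minimize(
        fun,
        theta0,
        jac=jac,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
    )
    theta = res.x
    beta, log_sigma = theta[:-1], theta[-1]
    ll, u, W, _ = marginal_loglik(
        beta, log_sigma, X, y, n, gidx, n_groups, n_nodes, return_parts=True
    )

    # boundary check: a vanishing random effect must not beat the optimum
    ll_zero = marginal_loglik(beta, -20.0, X, y, n, gidx, n_groups, n_nodes)
    if ll_zero > ll:
        ll, log_sigma = ll_zero, -20.0

    def negll(th):
        return -marginal_loglik(th[:-1], th[-1], X, y, n, gidx, n_groups, n_nodes)

    hess = numdiff.approx_hess3(theta, negll)
    p_fix = X.shape[1]
    # pseudo-inverse: separated cells make the information singular in
    # their interaction directions; those get zero variance and their
    # inference is suppressed downstream
    vcov_full = np.linalg.pinv(0.5 * (hess + hess.T))
    vcov_beta = vcov_full[:p_fix, :p_fix]
    vcov_beta = 0.5 * (vcov_beta + vcov_beta.T)

    if jac:
        _, g = fun(theta)
        grad_max = float(np.max(np.abs(g)))
    else:
        g = optimize.approx_fprime(theta, lambda th: -marginal_loglik(
            th[:-1], th[-1], X, y, n, gidx, n_groups, n_nodes), 1e-6)
        grad_max = float(np.max(np.abs(g)))

    return GLMMFit(
        design=design,
        beta=beta,
        sigma_u=float(np.exp(log_sigma)),
        vcov_beta=vcov_beta,
        loglik=float(ll),
        converged=bool(res.success) or grad_max < 1e-3,
        n_quadrature_nodes=n_nodes,
        n_iter=int(res.nit),
        grad_max=grad_max,
        u_modes=u,
        separated_cells=_detect_separation(design),
    )


def fixed_parameter_fit(design: GLMMDesign, beta, sigma_u: float) -> GLMMFit:
    """Wrap known parameters as a :class:`GLMMFit` without estimating.

    Used to simulate or diagnose at externally specified (e.g. true
    generating) parameter values.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != design.X.shape[1]:
        raise ValueError("beta length must match design columns")
    X, y, n, gidx = _aggregate(design)
    log_sigma = np.log(sigma_u) if sigma_u > 0 else -20.0
    ll, u, _, _ = marginal_loglik(
        beta, log_sigma, X, y, n, gidx, design.n_groups, return_parts=True
    )
    p = X.shape[1]
    return GLMMFit(
        design=design,
        beta=beta,
        sigma_u=float(sigma_u),
        vcov_beta=np.full((p, p), np.nan),
        loglik=float(ll),
        converged=True,
        n_quadrature_nodes=1,
        n_iter=0,
        grad_max=np.nan,
        u_modes=u,
        separated_cells=[],
    )


def brute_force_loglik(
    beta, sigma_u, design: GLMMDesign, span: float = 12.0, n_grid: int = 20001
) -> float:
    """Marginal log-likelihood by dense fixed-grid integration over u.

    Independent oracle for the Laplace/AGQ machinery: integrates the
    joint density per country on a uniform grid of width ``span`` prior
    standard deviations (trapezoid rule in log space).
    """
    X, y, n, gidx = _aggregate(design)
    n_groups = design.n_groups
    if sigma_u <= 0:
        eta = X @ beta
        return float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))
    grid = np.linspace(-span * sigma_u, span * sigma_u, n_grid)
    du = grid[1] - grid[0]
    eta0 = X @ beta
    total = 0.0
    for g in range(n_groups):
        sel = gidx == g
        eta = eta0[sel][:, None] + grid[None, :]
        ll = np.sum(y[sel][:, None] * eta - n[sel][:, None] * np.logaddexp(0.0, eta), axis=0)
        logf = ll - grid**2 / (2 * sigma_u**2) - 0.5 * np.log(2 * np.pi * sigma_u**2)
        total += logsumexp(logf) + np.log(du)
    return float(total)
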