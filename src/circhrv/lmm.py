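"""Profiled-REML solver for the random-intercept linear mixed model.

Model: y_ij = x_ij' beta + b_i + e_ij with b_i ~ N(0, tau^2) and
e_ij ~ N(0, sigma^2), independent across subjects i.  For a fixed variance
ratio lambda = tau^2 / sigma^2 the GLS estimate and the restricted
likelihood have closed forms in per-subject cross-products, so the fit
reduces to a one-dimensional optimization over lambda.

The per-subject sufficient statistics (n_i, X_i'X_i, X_i'y_i, column sums,
y_i'y_i) fully determine the fit.  That makes the subject-level bootstrap
nearly free: resampling subjects with replacement just re-sums a multiset
of precomputed statistics, and duplicated subjects are correctly treated as
independent clusters.  This is the hot path behind the bootstrap and the
Monte-Carlo calibration checks; the general random-(intercept, x, z) model
goes through statsmodels MixedLM instead, and the two routes are
cross-validated in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["SubjectStats", "RandomInterceptFit", "subject_stats", "fit_reml", "fit_ols"]


@dataclass(frozen=True)
class SubjectStats:
    """Per-subject cross-products sufficient for the random-intercept fit."""

    n: int
    xtx: np.ndarray  # (p, p)
    xty: np.ndarray  # (p,)
    xsum: np.ndarray  # (p,) column sums of X_i
    ysum: float
    yty: float


@dataclass
class RandomInterceptFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float  # residual variance
    tau2: float  # random-intercept variance
    reml: float  # -2 * restricted log-likelihood (up to a constant)
    converged: bool


def subject_stats(X: np.ndarray, y: np.ndarray) -> SubjectStats:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return SubjectStats(
        n=X.shape[0],
        xtx=X.T @ X,
        xty=X.T @ y,
        xsum=X.sum(axis=0),
        ysum=float(y.sum()),
        yty=float(y @ y),
    )


class _Pooled:
    """Stacked per-subject statistics; the lambda-independent totals are
    precomputed so each REML objective evaluation is a few vectorized ops."""

    def __init__(self, stats: list[SubjectStats]):
        self.n = np.array([s.n for s in stats], dtype=float)
        self.xsum = np.stack([s.xsum for s in stats])  # (n_subj, p)
        self.ysum = np.array([s.ysum for s in stats])
        self.xtx_tot = sum(s.xtx for s in stats)
        self.xty_tot = sum(s.xty for s in stats)
        self.yty_tot = float(sum(s.yty for s in stats))
        self.n_total = int(self.n.sum())


def _assemble(pooled: _Pooled, lam: float):
    """Pooled GLS normal equations and weighted sums at variance ratio lam."""
    c = lam / (1.0 + lam * pooled.n)  # (n_subj,)
    A = pooled.xtx_tot - pooled.xsum.T @ (c[:, None] * pooled.xsum)
    b = pooled.xty_tot - pooled.xsum.T @ (c * pooled.ysum)
    syy = pooled.yty_tot - float(c @ pooled.ysum**2)
    logdet_v = float(np.log1p(lam * pooled.n).sum())
    return A, b, syy, logdet_v


def _reml_criterion(pooled: _Pooled, lam: float, n_total: int):
    A, b, syy, logdet_v = _assemble(pooled, lam)
    p = A.shape[0]
    try:
        cho = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        # large finite penalty keeps the 1-D optimizer well behaved
        return 1e300, None, None, None
    beta = np.linalg.solve(A, b)
    rss = syy - b @ beta
    dof = n_total - p
    if rss <= 0:  # degenerate (e.g. noiseless) data
        rss = max(rss, 1e-300)
    sigma2 = rss / dof
    logdet_a = 2.0 * np.log(np.diag(cho)).sum()
    crit = dof * np.log(sigma2) + logdet_v + logdet_a
    return crit, beta, sigma2, A


def fit_reml(stats: list[SubjectStats]) -> RandomInterceptFit:
    """REML fit by 1-D optimization of the profiled criterion over log-lambda.

    lambda is searched on [1e-10, 1e8]; a boundary solution at the lower end
    collapses to ordinary least squares (tau^2 = 0).
    """
    pooled = _Pooled(stats)
    n_total = pooled.n_total

    def objective(log_lam: float) -> float:
        return _reml_criterion(pooled, np.exp(log_lam), n_total)[0]

    # Coarse bracket on a log grid, then Brent refinement.
    grid = np.linspace(np.log(1e-10), np.log(1e8), 19)
    values = [objective(g) for g in grid]
    k = int(np.argmin(values))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded")
    lam = float(np.exp(res.x))
    crit, beta, sigma2, A = _reml_criterion(pooled, lam, n_total)
    if beta is None:
        raise np.linalg.LinAlgError("rank-deficient design in mixed-model fit")
    cov_beta = sigma2 * np.linalg.inv(A)
    return RandomInterceptFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        tau2=float(lam * sigma2),
        reml=float(crit),
        converged=bool(res.success),
    )


def fit_ols(stats: list[SubjectStats]) -> RandomInterceptFit:
    """Ordinary least squares on the pooled data (no random effects)."""
    pooled = _Pooled(stats)
    n_total = pooled.n_total
    crit, beta, sigma2, A = _reml_criterion(pooled, 0.0, n_total)
    if beta is None:
        raise np.linalg.LinAlgError("rank-deficient design in least-squares fit")
    return RandomInterceptFit(
        beta=beta,
        cov_beta=sigma2 * np.linalg.inv(A),
        sigma2=float(sigma2),
        tau2=0.0,
        reml=float(crit),
        converged=True,
    )
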