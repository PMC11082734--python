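"""Single-rhythm and mixed-effect cosinor estimation for 24-h SDNN rhythms.

The cosinor model describes a circadian signal as

    Y(t) = M + A * cos(2*pi*t/tau + phi) + e(t),      tau = 24 h,

with MESOR M (rhythm-adjusted 24-h mean), amplitude A (half the
peak-to-trough extent) and acrophase phi (phase angle of the daily peak).
Expanding the cosine turns this into a linear model in x = cos(2*pi*t/tau)
and z = sin(2*pi*t/tau):

    Y(t) = M + beta * x + gamma * z + e(t),
    beta = A * cos(phi),   gamma = -A * sin(phi),

so ordinary least squares on (1, x, z) is exactly nonlinear least squares
on the cosine model.  The longitudinal extension adds per-subject random
effects theta_i ~ MVN(0, Sigma) on (intercept, x, z) to absorb the
within-subject correlation of repeated days, a window factor (baseline as
reference) interacted with (1, x, z) so every 7-day study window gets its
own rhythm, and age/sex/BMI acting on the MESOR.

Acrophase is stored in (-2*pi, 0] radians, the convention in which the
clock time of the daily peak is -phi * tau / (2*pi) in [0, 24).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import lmm
from .data_model import (
    HRVSample,
    StudyWindow,
    SubjectProfile,
    day_offset,
    default_windows,
)

__all__ = [
    "CircadianParams",
    "LinearCosinorCoefs",
    "FitOptions",
    "MixedCosinorFit",
    "FitError",
    "time_to_angle",
    "cosinor_predict",
    "params_to_coefs",
    "coefs_to_params",
    "wrap_acrophase",
    "hours_of_day",
    "fit_single_cosinor",
    "fit_mixed_cosinor",
    "samples_to_frame",
]

#: Amplitude below which the rhythm is reported as degenerate (phase
#: unidentifiable); in ms, far below any physiologically meaningful rhythm.
DEGENERATE_AMPLITUDE = 1e-8


class FitError(RuntimeError):
    """Raised when a cosinor fit cannot be computed on the given data."""


@dataclass(frozen=True)
class CircadianParams:
    """One 24-h rhythm: (MESOR, amplitude, acrophase, period)."""

    mesor: float
    amplitude: float
    acrophase: float
    period: float = 24.0
    degenerate: bool = False  # amplitude ~ 0, acrophase meaningless

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not (-2 * np.pi < self.acrophase <= 0):
            raise ValueError(
                f"acrophase must lie in (-2*pi, 0], got {self.acrophase}"
            )
        if self.period <= 0:
            raise ValueError(f"period must be > 0, got {self.period}")

    @property
    def peak_time(self) -> float:
        """Clock time (hours) of the fitted daily peak."""
        return -self.acrophase * self.period / (2 * np.pi)


@dataclass(frozen=True)
class LinearCosinorCoefs:
    """Linearized cosinor coefficients (intercept, beta, gamma)."""

    mesor: float
    beta: float
    gamma: float
    period: float = 24.0


def time_to_angle(t, period: float = 24.0):
    """Map clock time to the unit-circle design pair (x, z).

    x = cos(2*pi*t/period), z = sin(2*pi*t/period); x**2 + z**2 == 1.
    """
    if period <= 0:
        raise ValueError(f"period must be > 0, got {period}")
    angle = 2 * np.pi * np.asarray(t, dtype=float) / period
    return np.cos(angle), np.sin(angle)


def cosinor_predict(p: CircadianParams, t) -> np.ndarray | float:
    """Noise-free mean M + A*cos(2*pi*t/tau + phi) at clock time(s) t."""
    t = np.asarray(t, dtype=float)
    out = p.mesor + p.amplitude * np.cos(2 * np.pi * t / p.period + p.acrophase)
    return float(out) if out.ndim == 0 else out


def wrap_acrophase(phi: float) -> float:
    """Map any phase angle into the stored branch (-2*pi, 0]."""
    phi = float(np.mod(phi, 2 * np.pi))  # [0, 2*pi)
    return phi - 2 * np.pi if phi > 0 else phi


def params_to_coefs(p: CircadianParams) -> LinearCosinorCoefs:
    return LinearCosinorCoefs(
        mesor=p.mesor,
        beta=p.amplitude * np.cos(p.acrophase),
        gamma=-p.amplitude * np.sin(p.acrophase),
        period=p.period,
    )


def coefs_to_params(c: LinearCosinorCoefs) -> CircadianParams:
    """Invert the linearization: A = sqrt(beta^2 + gamma^2), phi = atan2(-gamma, beta).

    A zero-amplitude rhythm has no phase; it is returned with phi = 0 and
    the ``degenerate`` flag set.
    """
    amplitude = float(np.hypot(c.beta, c.gamma))
    if amplitude < DEGENERATE_AMPLITUDE:
        return CircadianParams(c.mesor, amplitude, 0.0, c.period, degenerate=True)
    phi = wrap_acrophase(np.arctan2(-c.gamma, c.beta))
    return CircadianParams(c.mesor, amplitude, phi, c.period)


def hours_of_day(timestamps: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Clock time as fractional hours since local midnight of each sample's date."""
    ts = pd.DatetimeIndex(timestamps)
    return (
        ts.hour + ts.minute / 60 + ts.second / 3600 + ts.microsecond / 3.6e9
    ).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Single-subject fit


def fit_single_cosinor(
    t, y, period: float = 24.0
) -> tuple[CircadianParams, np.ndarray]:
    """OLS cosinor fit of one subject-window; returns params and the 3x3
    covariance of (M, beta, gamma).

    Equivalent to nonlinear least squares of M + A*cos(2*pi*t/tau + phi)
    because the linearization is exact.  Requires at least 4 samples at
    3 distinct clock times; with all samples at a single clock time the
    design is rank deficient and the rhythm is not identifiable.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if len(t) < 4:
        raise FitError(f"need >= 4 samples to fit a cosinor, got {len(t)}")
    x, z = time_to_angle(np.mod(t, period), period)
    X = np.column_stack([np.ones_like(x), x, z])
    if np.linalg.matrix_rank(X) < 3:
        raise FitError(
            "rank-deficient cosinor design: samples cover too few distinct "
            "clock times (need >= 3) to identify the rhythm"
        )
    beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - 3, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    params = coefs_to_params(LinearCosinorCoefs(beta[0], beta[1], beta[2], period))
    return params, cov


# ---------------------------------------------------------------------------
# Mixed-effect fit


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_mixed_cosinor`.

    re_structure
        "intercept_xz" — per-subject random (intercept, x, z) with
        unstructured covariance (statsmodels MixedLM, REML);
        "intercept" — random intercept only (fast profiled-REML solver);
        "none" — plain pooled least squares.
    fallback_to_intercept
        On non-convergence of the full model, refit with a random
        intercept only instead of raising; recorded in the fit metadata.
    use_covariates
        Include centered age/BMI and sex on the MESOR.
    """

    re_structure: str = "intercept_xz"
    fallback_to_intercept: bool = True
    use_covariates: bool = True
    maxiter: int = 200
    period: float = 24.0

    def __post_init__(self):
        if self.re_structure not in ("intercept_xz", "intercept", "none"):
            raise ValueError(f"unknown re_structure {self.re_structure!r}")


@dataclass
class MixedCosinorFit:
    """Joint mixed-effect cosinor fit across study windows.

    ``window_params`` maps each window label to its derived
    :class:`CircadianParams` (week-k parameters are baseline coefficients
    plus the window-interaction contrasts).  ``re_cov`` is the estimated
    random-effect covariance Sigma (1x1 for a random intercept).
    """

    window_params: dict[str, CircadianParams]
    coef: pd.Series
    cov_coef: pd.DataFrame
    re_cov: np.ndarray
    resid_var: float
    n_subjects: int
    n_samples: int
    converged: bool
    engine: str
    fallback_used: bool
    centering: dict[str, float]
    options: FitOptions
    window_labels: list[str] = field(default_factory=list)


def samples_to_frame(
    samples: Iterable[HRVSample] | pd.DataFrame,
    profiles: Iterable[SubjectProfile] | pd.DataFrame,
    windows: Sequence[StudyWindow] | None = None,
) -> pd.DataFrame:
    """Long modelling frame: one row per in-window sample.

    Columns: subject_id, t (hours since midnight), sdnn_ms, window, age,
    sex, bmi.  Samples outside every window are dropped.
    """
    windows = list(windows) if windows is not None else default_windows()
    if isinstance(profiles, pd.DataFrame):
        prof_df = profiles.copy()
        prof_df["intervention_start"] = pd.to_datetime(
            prof_df["intervention_start"]
        ).dt.date
    else:
        prof_df = pd.DataFrame(
            [
                {
                    "subject_id": p.subject_id,
                    "age": p.age,
                    "sex": p.sex,
                    "bmi": p.bmi,
                    "intervention_start": p.intervention_start,
                }
                for p in profiles
            ]
        )
    if isinstance(samples, pd.DataFrame):
        samp_df = samples.copy()
        samp_df["timestamp"] = pd.to_datetime(samp_df["timestamp"])
    else:
        samp_df = pd.DataFrame(
            [
                {"subject_id": s.subject_id, "timestamp": s.timestamp, "sdnn_ms": s.sdnn_ms}
                for s in samples
            ]
        )
    df = samp_df.merge(prof_df, on="subject_id", how="inner")
    offsets = np.array(
        [
            day_offset(ts, start)
            for ts, start in zip(df["timestamp"], df["intervention_start"])
        ]
    )
    label = np.full(len(df), "", dtype=object)
    for w in windows:
        lo, hi = w.day_range
        label[(offsets >= lo) & (offsets < hi)] = w.label
    df["window"] = label
    df = df[df["window"] != ""].copy()
    df["t"] = hours_of_day(df["timestamp"])
    return df[["subject_id", "t", "sdnn_ms", "window", "age", "sex", "bmi"]]


def _window_order(labels: Iterable[str]) -> list[str]:
    present = set(labels)
    ordered = [w.label for w in default_windows() if w.label in present]
    ordered += sorted(present - set(ordered))
    return ordered


def build_design(
    df: pd.DataFrame,
    options: FitOptions,
    centering: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, float], list[str]]:
    """Fixed-effect design: window factor x (1, x, z) + centered covariates.

    The first window in study order is the reference; its rhythm lives in
    (intercept, x, z) and each later window w adds contrast columns
    (w, w:x, w:z).  Covariates are centered at subject-level means so the
    intercept is the adjusted MESOR for an average subject; the centering
    constants are returned (and reusable) so bootstrap refits keep the
    estimand fixed at the original cohort's covariate means.
    """
    labels = _window_order(df["window"])
    x, z = time_to_angle(df["t"].to_numpy(), options.period)
    cols = [np.ones(len(df)), x, z]
    names = ["intercept", "x", "z"]
    for w in labels[1:]:
        d = (df["window"] == w).to_numpy(dtype=float)
        cols += [d, d * x, d * z]
        names += [w, f"{w}:x", f"{w}:z"]
    if options.use_covariates:
        per_subject = df.drop_duplicates("subject_id")
        male = (df["sex"] == "male").to_numpy(dtype=float)
        if centering is None:
            centering = {
                "age": float(per_subject["age"].mean()),
                "bmi": float(per_subject["bmi"].mean()),
                "male": float((per_subject["sex"] == "male").mean()),
            }
        # Covariate columns with no variation (e.g. a single subject, or an
        # all-female stratum) carry no information and would make the
        # design rank deficient; they are dropped.
        for col, name in [
            (df["age"].to_numpy(dtype=float) - centering["age"], "age_c"),
            (df["bmi"].to_numpy(dtype=float) - centering["bmi"], "bmi_c"),
            (male - centering["male"], "male_c"),
        ]:
            if np.ptp(col) > 1e-12:
                cols.append(col)
                names.append(name)
    else:
        centering = {}
    X = np.column_stack(cols)
    y = df["sdnn_ms"].to_numpy(dtype=float)
    return X, y, names, centering, labels


def _derive_window_params(
    coef: pd.Series, labels: list[str], period: float
) -> dict[str, CircadianParams]:
    out = {}
    base = np.array([coef["intercept"], coef["x"], coef["z"]])
    out[labels[0]] = coefs_to_params(
        LinearCosinorCoefs(base[0], base[1], base[2], period)
    )
    for w in labels[1:]:
        m, b, g = base + np.array([coef[w], coef[f"{w}:x"], coef[f"{w}:z"]])
        out[w] = coefs_to_params(LinearCosinorCoefs(m, b, g, period))
    return out


def _fit_intercept_engine(X, y, groups, names, engine: str):
    stats = []
    gvals = np.asarray(groups)
    for g in pd.unique(gvals):
        mask = gvals == g
        stats.append(lmm.subject_stats(X[mask], y[mask]))
    if engine == "none":
        return lmm.fit_ols(stats)
    return lmm.fit_reml(stats)


def fit_mixed_cosinor(
    samples,
    profiles,
    windows: Sequence[StudyWindow] | None = None,
    options: FitOptions | None = None,
) -> MixedCosinorFit:
    """Fit the joint mixed-effect cosinor model across study windows.

    One linear mixed model is fitted to all windows at once: window factor
    (baseline reference) interacted with (1, x, z), centered age/BMI and
    sex on the intercept, and per-subject random effects.  Sharing the
    variance components across windows is what lets each week be compared
    with baseline on a common scale.
    """
    options = options or FitOptions()
    df = samples_to_frame(samples, profiles, windows)
    if df.empty:
        raise FitError("no in-window samples to fit")
    n_subjects = df["subject_id"].nunique()
    if options.re_structure != "none" and n_subjects < 2:
        raise FitError(
            "mixed-effect cosinor needs >= 2 subjects; use re_structure='none' "
            "or fit_single_cosinor for a single subject"
        )
    X, y, names, centering, labels = build_design(df, options)
    groups = df["subject_id"].to_numpy()

    engine = options.re_structure
    fallback_used = False
    re_cov = np.zeros((1, 1))
    if engine == "intercept_xz":
        result = _fit_statsmodels(X, y, groups, df, options)
        if result is None:
            if not options.fallback_to_intercept:
                raise FitError(
                    "random-(intercept,x,z) model failed to converge; "
                    "re-run with fallback_to_intercept=True or "
                    "re_structure='intercept'"
                )
            fallback_used = True
            engine = "intercept"
        else:
            beta, cov_beta, re_cov, sigma2, converged = result
    if engine in ("intercept", "none"):
        fit = _fit_intercept_engine(X, y, groups, names, engine)
        beta, cov_beta, sigma2 = fit.beta, fit.cov_beta, fit.sigma2
        re_cov = np.array([[fit.tau2]])
        converged = fit.converged

    coef = pd.Series(beta, index=names)
    cov = pd.DataFrame(cov_beta, index=names, columns=names)
    return MixedCosinorFit(
        window_params=_derive_window_params(coef, labels, options.period),
        coef=coef,
        cov_coef=cov,
        re_cov=np.asarray(re_cov),
        resid_var=float(sigma2),
        n_subjects=int(n_subjects),
        n_samples=len(df),
        converged=bool(converged),
        engine=engine,
        fallback_used=fallback_used,
        centering=centering,
        options=options,
        window_labels=labels,
    )


def _fit_statsmodels(X, y, groups, df, options: FitOptions):
    """Random-(intercept, x, z) REML via statsmodels; None on failure."""
    import statsmodels.api as sm

    exog_re = X[:, :3]  # (1, x, z) columns
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
            res = model.fit(reml=True, maxiter=options.maxiter)
        if not res.converged or not np.all(np.isfinite(res.fe_params)):
            return None
        k = X.shape[1]
        return (
            np.asarray(res.fe_params),
            np.asarray(res.cov_params())[:k, :k],
            np.asarray(res.cov_re),
            float(res.scale),
            True,
        )
    except (np.linalg.LinAlgError, ValueError):
        return None
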