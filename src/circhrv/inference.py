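"""Subject-level bootstrap inference for circadian parameters.

Uncertainty in the mixed-effect cosinor estimates is quantified with a
cluster (subject-level) bootstrap: subjects are resampled with
replacement, the model is refitted on each resample (duplicated subjects
count as independent clusters), and percentile intervals are read off the
replicate distribution of each window's (MESOR, amplitude, acrophase) and
of each window-minus-baseline difference.  Resampling whole subjects
respects the within-subject correlation that the mixed model exists for.

Acrophase differences are computed on the circle and wrapped to
(-pi, pi], so a rhythm drifting across the branch cut never produces a
spurious 2*pi jump.

The two-sided bootstrap p-value for a difference d uses the +1 continuity
correction, p = 2 * min(#(d* <= 0) + 1, #(d* >= 0) + 1) / (B + 1), floored
at 2 / (B + 1); with percentile intervals this p agrees with whether the
1 - alpha interval excludes zero, up to the discrete bootstrap grid.

For random-intercept (or no-random-effect) fits the refits run on
precomputed per-subject sufficient statistics (see :mod:`circhrv.lmm`), so
a 1000-replicate bootstrap costs about a second; the full
random-(intercept, x, z) model refits through statsmodels and is
correspondingly slower.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from . import lmm
from .cosinor import (
    FitError,
    FitOptions,
    MixedCosinorFit,
    _derive_window_params,
    _fit_statsmodels,
    build_design,
    fit_mixed_cosinor,
    samples_to_frame,
)

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "ComparisonResult",
    "PARAMETERS",
    "bootstrap_fit",
    "compare_to_baseline",
    "comparison_table",
    "window_difference",
]

PARAMETERS = ("MESOR", "amplitude", "acrophase")


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    resample_unit: str = "subject"

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError(f"n_boot must be >= 1, got {self.n_boot}")
        if not (0 < self.ci_level < 1):
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.resample_unit != "subject":
            raise ValueError("only subject-level resampling is supported")


@dataclass
class BootstrapResult:
    """Replicate distributions of per-window parameters and differences.

    ``samples[param]`` is a (n_used, n_windows) array of replicate values;
    ``diffs[param]`` the matching window-minus-baseline differences
    (acrophase wrapped on the circle).  Replicates whose refit failed are
    dropped and counted in ``n_dropped``; ``high_drop_warning`` is set when
    more than 10% were lost.
    """

    fit: MixedCosinorFit
    config: BootstrapConfig
    window_labels: list[str]
    samples: dict[str, np.ndarray]
    diffs: dict[str, np.ndarray]
    n_boot_used: int
    n_dropped: int
    high_drop_warning: bool


@dataclass(frozen=True)
class ComparisonResult:
    """One window-vs-baseline contrast for one circadian parameter."""

    window: str
    parameter: str
    estimate: float
    estimate_ci: tuple[float, float]
    difference: float
    difference_ci: tuple[float, float]
    p_value: float
    n_boot_used: int


def _param_array(params_by_window: dict, labels: list[str]) -> np.ndarray:
    """(3, n_windows) array of (MESOR, amplitude, acrophase)."""
    return np.array(
        [
            [params_by_window[w].mesor for w in labels],
            [params_by_window[w].amplitude for w in labels],
            [params_by_window[w].acrophase for w in labels],
        ]
    )


def _wrap_to_pi(delta):
    """Wrap angular difference(s) into (-pi, pi]."""
    out = np.mod(-np.asarray(delta) + np.pi, 2 * np.pi)
    return -(out - np.pi)


def bootstrap_fit(
    samples,
    profiles,
    windows=None,
    fit_options: FitOptions | None = None,
    cfg: BootstrapConfig | None = None,
) -> BootstrapResult:
    """Cluster bootstrap of the mixed cosinor fit.

    The original-data fit anchors the design (window labels and covariate
    centering); every replicate refits the same design on a with-replacement
    sample of subjects.  Deterministic given ``cfg.seed``.
    """
    fit_options = fit_options or FitOptions()
    cfg = cfg or BootstrapConfig()
    fit = fit_mixed_cosinor(samples, profiles, windows, fit_options)
    df = samples_to_frame(samples, profiles, windows)
    X, y, names, _, labels = build_design(df, fit_options, centering=fit.centering)
    groups = df["subject_id"].to_numpy()
    subject_ids = pd.unique(groups)
    row_index = {g: np.flatnonzero(groups == g) for g in subject_ids}

    fast = fit.engine in ("intercept", "none")
    if fast:
        stats_by_subject = {
            g: lmm.subject_stats(X[row_index[g]], y[row_index[g]])
            for g in subject_ids
        }

    rng = np.random.default_rng(cfg.seed)
    period = fit_options.period
    reps = []
    n_dropped = 0
    for _ in range(cfg.n_boot):
        draw = rng.choice(subject_ids, size=len(subject_ids), replace=True)
        try:
            if fast:
                stats = [stats_by_subject[g] for g in draw]
                rfit = lmm.fit_ols(stats) if fit.engine == "none" else lmm.fit_reml(stats)
                coef = pd.Series(rfit.beta, index=names)
            else:
                coef = _statsmodels_replicate(X, y, row_index, draw, names, fit_options)
                if coef is None:
                    n_dropped += 1
                    continue
            params = _derive_window_params(coef, labels, period)
        except (np.linalg.LinAlgError, FitError):
            n_dropped += 1
            continue
        reps.append(_param_array(params, labels))

    if not reps:
        raise FitError("every bootstrap replicate failed to refit")
    arr = np.stack(reps)  # (n_used, 3, n_windows)
    samples_out = {p: arr[:, i, :] for i, p in enumerate(PARAMETERS)}
    diffs = {
        "MESOR": samples_out["MESOR"] - samples_out["MESOR"][:, [0]],
        "amplitude": samples_out["amplitude"] - samples_out["amplitude"][:, [0]],
        "acrophase": _wrap_to_pi(
            samples_out["acrophase"] - samples_out["acrophase"][:, [0]]
        ),
    }
    return BootstrapResult(
        fit=fit,
        config=cfg,
        window_labels=labels,
        samples=samples_out,
        diffs=diffs,
        n_boot_used=len(reps),
        n_dropped=n_dropped,
        high_drop_warning=n_dropped > 0.1 * cfg.n_boot,
    )


def _statsmodels_replicate(X, y, row_index, draw, names, fit_options):
    rows = []
    groups = []
    for k, g in enumerate(draw):
        idx = row_index[g]
        rows.append(idx)
        groups.append(np.full(len(idx), k))
    idx = np.concatenate(rows)
    result = _fit_statsmodels(
        X[idx], y[idx], np.concatenate(groups), None, fit_options
    )
    if result is None:
        return None
    return pd.Series(result[0], index=names)


def window_difference(
    point_estimates, window: str, baseline: str = "baseline", circular: bool = False
) -> float:
    """Window-minus-baseline difference of point estimates.

    This is the differencing convention used throughout: the reported
    difference is estimate(window) - estimate(baseline) from the
    original-data fit, wrapped to (-pi, pi] for circular (acrophase)
    parameters.
    """
    d = float(point_estimates[window]) - float(point_estimates[baseline])
    return float(_wrap_to_pi(d)) if circular else d


def compare_to_baseline(
    boot: BootstrapResult,
    window: str,
    parameter: str,
    ci_level: float | None = None,
) -> ComparisonResult:
    """Percentile CI and bootstrap p for one window-vs-baseline contrast.

    The point difference comes from the original-data fit; the CI from the
    replicate distribution of differences.  Comparing the baseline window
    to itself is the identity contrast (difference 0, p = 1).
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; expected {PARAMETERS}")
    if window not in boot.window_labels:
        raise ValueError(f"unknown window {window!r}")
    ci_level = boot.config.ci_level if ci_level is None else ci_level
    alpha = 1 - ci_level
    j = boot.window_labels.index(window)
    baseline = boot.window_labels[0]

    point = _param_array(boot.fit.window_params, boot.window_labels)[
        PARAMETERS.index(parameter), j
    ]
    est_ci = tuple(
        np.quantile(boot.samples[parameter][:, j], [alpha / 2, 1 - alpha / 2])
    )
    if window == baseline:
        return ComparisonResult(
            window, parameter, float(point), est_ci, 0.0, (0.0, 0.0), 1.0,
            boot.n_boot_used,
        )

    points = dict(
        zip(
            boot.window_labels,
            _param_array(boot.fit.window_params, boot.window_labels)[
                PARAMETERS.index(parameter)
            ],
        )
    )
    diff = window_difference(
        points, window, baseline, circular=parameter == "acrophase"
    )
    d = boot.diffs[parameter][:, j]
    lo, hi = np.quantile(d, [alpha / 2, 1 - alpha / 2])
    b = len(d)
    p = 2 * min((np.sum(d <= 0) + 1) / (b + 1), (np.sum(d >= 0) + 1) / (b + 1))
    p = float(min(max(p, 2 / (b + 1)), 1.0))
    return ComparisonResult(
        window, parameter, float(point), est_ci, float(diff),
        (float(lo), float(hi)), p, boot.n_boot_used,
    )


def comparison_table(
    boot: BootstrapResult, ci_level: float | None = None
) -> pd.DataFrame:
    """All window x parameter contrasts as a tidy frame (the per-stratum
    layout of a weekly circadian-parameter comparison table)."""
    rows = []
    for parameter in PARAMETERS:
        for window in boot.window_labels:
            r = compare_to_baseline(boot, window, parameter, ci_level)
            is_base = window == boot.window_labels[0]
            rows.append(
                {
                    "parameter": r.parameter,
                    "window": r.window,
                    "mean": r.estimate,
                    "mean_ci_lo": r.estimate_ci[0],
                    "mean_ci_hi": r.estimate_ci[1],
                    "difference": np.nan if is_base else r.difference,
                    "diff_ci_lo": np.nan if is_base else r.difference_ci[0],
                    "diff_ci_hi": np.nan if is_base else r.difference_ci[1],
                    "p_value": np.nan if is_base else r.p_value,
                }
            )
    return pd.DataFrame(rows)
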