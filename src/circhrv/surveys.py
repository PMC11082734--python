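"""Scoring and longitudinal analysis of the six psychological instruments.

Instruments and raw-sum score ranges:

* CD-RISC 10 — resilience; 10 items on a 0-4 Likert scale, total 0-40,
  higher = more resilient.
* PROMIS emotional support (2 items, 1-5 each, total 2-10, higher = more
  perceived support).
* PSS-10 — perceived stress; 10 items 0-4, items 4, 5, 7, 8 (1-based, the
  positively worded ones) reverse-scored, total 0-40, higher = more stress.
* 2-item Global Health / Quality of Life (1-5 each, total 2-10); scored so
  that higher totals mean better health and quality of life.
* PHQ-4 — anxiety/depression screen; 4 items 0-3, total 0-12, higher =
  more impairment.
* NIH PROMIS positive affect and well-being (23 items 1-5, total 23-115,
  higher = more positive affect).

Reverse scoring replaces an item value v by (range_max + range_min - v),
which is an involution.  Longitudinal change is analysed per instrument
and compliance stratum with a linear mixed model (score ~ timepoint
factor, random subject intercept); strata too small to support the model
yield a not-estimable marker rather than a number, mirroring how
underpowered subgroups are reported in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import ValidationError

__all__ = [
    "InstrumentSpec",
    "SurveyResponse",
    "SurveyScore",
    "INSTRUMENTS",
    "TIMEPOINTS",
    "reverse_item",
    "score",
    "score_frame",
    "longitudinal_change",
]

#: Survey timepoints in study order.
TIMEPOINTS = ("baseline", "week5", "week7", "week17")


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    n_items: int
    item_range: tuple[int, int]  # inclusive
    reverse_items: tuple[int, ...] = ()  # 1-based item indices
    direction: str = "higher_better"  # or "higher_worse"

    @property
    def total_range(self) -> tuple[int, int]:
        lo, hi = self.item_range
        return self.n_items * lo, self.n_items * hi


INSTRUMENTS: dict[str, InstrumentSpec] = {
    s.name: s
    for s in [
        InstrumentSpec("cdrisc10", 10, (0, 4)),
        InstrumentSpec("promis_support", 2, (1, 5)),
        InstrumentSpec("pss10", 10, (0, 4), reverse_items=(4, 5, 7, 8),
                       direction="higher_worse"),
        InstrumentSpec("global_health", 2, (1, 5)),
        InstrumentSpec("phq4", 4, (0, 3), direction="higher_worse"),
        InstrumentSpec("positive_affect", 23, (1, 5)),
    ]
}


@dataclass(frozen=True)
class SurveyResponse:
    subject_id: str
    timepoint: str
    instrument: str
    items: tuple[int, ...]

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )
        if self.instrument not in INSTRUMENTS:
            raise ValidationError(f"unknown instrument {self.instrument!r}")


@dataclass(frozen=True)
class SurveyScore:
    subject_id: str
    timepoint: str
    instrument: str
    total: int


def reverse_item(value: int, item_range: tuple[int, int]) -> int:
    lo, hi = item_range
    return hi + lo - value


def score(response: SurveyResponse) -> SurveyScore:
    """Raw-sum score with reverse-scored items flipped.

    Validates the item count and each item's range, naming the first
    offending item index (1-based) on failure.
    """
    spec = INSTRUMENTS[response.instrument]
    if len(response.items) != spec.n_items:
        raise ValidationError(
            f"{spec.name}: expected {spec.n_items} items, got {len(response.items)}"
        )
    lo, hi = spec.item_range
    total = 0
    reverse = set(spec.reverse_items)
    for idx, value in enumerate(response.items, start=1):
        if not (lo <= value <= hi):
            raise ValidationError(
                f"{spec.name}: item {idx} value {value} outside [{lo}, {hi}]"
            )
        total += reverse_item(value, spec.item_range) if idx in reverse else value
    return SurveyScore(response.subject_id, response.timepoint, spec.name, total)


def score_frame(responses: Iterable[SurveyResponse]) -> pd.DataFrame:
    """Score a batch of responses into a long frame
    (subject_id, timepoint, instrument, total)."""
    rows = [
        {
            "subject_id": s.subject_id,
            "timepoint": s.timepoint,
            "instrument": s.instrument,
            "total": s.total,
        }
        for s in map(score, responses)
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "timepoint", "instrument", "total"]
    )


NOT_ESTIMABLE = float("nan")


def _mixed_timepoint_pvalues(sub: pd.DataFrame) -> dict[str, float]:
    """Wald p-values for each follow-up-vs-baseline contrast from a
    random-intercept mixed model; NaN where the model cannot be fitted."""
    import statsmodels.api as sm

    levels = [t for t in TIMEPOINTS if (sub["timepoint"] == t).any()]
    followups = [t for t in levels if t != "baseline"]
    if "baseline" not in levels or not followups:
        return {t: NOT_ESTIMABLE for t in followups}
    if sub.loc[sub["timepoint"] != "baseline", "subject_id"].nunique() < 2:
        return {t: NOT_ESTIMABLE for t in followups}
    if float(np.var(sub["total"])) == 0.0:
        # No variation anywhere: every contrast is exactly zero.
        return {t: 1.0 for t in followups}
    X = np.column_stack(
        [np.ones(len(sub))]
        + [(sub["timepoint"] == t).to_numpy(dtype=float) for t in followups]
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                sub["total"].to_numpy(dtype=float),
                X,
                groups=sub["subject_id"].to_numpy(),
            )
            res = model.fit(reml=True)
        pvals = np.asarray(res.pvalues)[1 : 1 + len(followups)]
        return {t: float(p) for t, p in zip(followups, pvals)}
    except (np.linalg.LinAlgError, ValueError):
        return {t: NOT_ESTIMABLE for t in followups}


def longitudinal_change(
    scores: pd.DataFrame,
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-timepoint mean (SD) and change-from-baseline inference.

    ``scores`` is the long frame from :func:`score_frame`; ``subject_ids``
    restricts the analysis to one compliance stratum.  Returns one row per
    instrument and timepoint with columns n, mean, sd, change (vs the
    baseline mean) and p (mixed-model contrast; NaN = not estimable, and
    always NaN at baseline itself).
    """
    df = scores.copy()
    if subject_ids is not None:
        df = df[df["subject_id"].isin(set(subject_ids))]
    rows = []
    for instrument in INSTRUMENTS:
        sub = df[df["instrument"] == instrument]
        if sub.empty:
            continue
        enough = sub["subject_id"].nunique() >= 2 and (
            sub["timepoint"] == "baseline"
        ).any()
        pvals = _mixed_timepoint_pvalues(sub) if enough else {}
        base = sub.loc[sub["timepoint"] == "baseline", "total"]
        base_mean = float(base.mean()) if len(base) else NOT_ESTIMABLE
        for t in TIMEPOINTS:
            vals = sub.loc[sub["timepoint"] == t, "total"]
            if vals.empty:
                continue
            rows.append(
                {
                    "instrument": instrument,
                    "timepoint": t,
                    "n": int(len(vals)),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else NOT_ESTIMABLE,
                    "change": float(vals.mean()) - base_mean
                    if t != "baseline"
                    else 0.0,
                    "p": NOT_ESTIMABLE
                    if t == "baseline"
                    else pvals.get(t, NOT_ESTIMABLE),
                }
            )
    return pd.DataFrame(
        rows, columns=["instrument", "timepoint", "n", "mean", "sd", "change", "p"]
    )
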