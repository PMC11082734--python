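"""Core record types, CSV I/O, study-window assignment, and compliance.

The study timeline is anchored at each subject's intervention start date.
Day offsets are *local calendar-date* differences (a session and a wear day
are calendar-day phenomena), so a sample at 23:59 the day before the
intervention starts still belongs to the last baseline day.  Windows are
half-open 7-day blocks: baseline covers day offsets [-7, 0) and week k
covers [7(k-1), 7k) for k = 1..7; the wearable observation period ends
after week 7, so later samples are labelled out-of-window.

Compliance counts distinct calendar days with a completed biofeedback
session inside the 35-day intervention period (one 5-minute session per day
for 5 weeks) and stratifies subjects at >0%, >=20% and >=50% of the 35
prescribed sessions.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HRVSample",
    "SubjectProfile",
    "SessionLog",
    "StudyWindow",
    "ComplianceSummary",
    "ValidationError",
    "EXPECTED_SESSIONS",
    "OUT_OF_WINDOW",
    "default_windows",
    "read_hrv",
    "write_hrv",
    "read_subjects",
    "write_subjects",
    "read_sessions",
    "write_sessions",
    "assign_windows",
    "compute_compliance",
    "stratify",
    "format_percent",
]

#: Prescribed number of biofeedback sessions: one per day for 5 weeks.
EXPECTED_SESSIONS = 35

#: Window label for samples outside the observation period.
OUT_OF_WINDOW = "out_of_window"

#: Compliance strata in nesting order, loosest first.
STRATA = (">0%", ">=20%", ">=50%")

HRV_COLUMNS = ["subject_id", "timestamp", "sdnn_ms", "window_s"]
SUBJECT_COLUMNS = ["subject_id", "age", "sex", "bmi", "intervention_start"]
SESSION_COLUMNS = ["subject_id", "session_date"]


class ValidationError(ValueError):
    """Raised when an input file or record violates its schema.

    Carries the list of offending row numbers (1-based, excluding the
    header) in ``rows`` when the failure is row-level.
    """

    def __init__(self, message: str, rows: Sequence[int] | None = None):
        self.rows = list(rows) if rows is not None else []
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


@dataclass(frozen=True)
class HRVSample:
    """One wearable SDNN measurement.

    ``timestamp`` is the local wall-clock time of the measurement (the
    device reports local time; no timezone conversion is performed) and
    ``window_s`` the length of the beat-interval window the SDNN was
    computed over (about 60 s for the wrist device emulated here).
    """

    subject_id: str
    timestamp: pd.Timestamp
    sdnn_ms: float
    window_s: float = 60.0

    def __post_init__(self):
        if not self.sdnn_ms > 0:
            raise ValidationError(f"sdnn_ms must be > 0, got {self.sdnn_ms}")
        if not self.window_s > 0:
            raise ValidationError(f"window_s must be > 0, got {self.window_s}")


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics and intervention anchor for one participant."""

    subject_id: str
    age: float
    sex: str  # "female" | "male"
    bmi: float
    intervention_start: date

    def __post_init__(self):
        if not self.age > 0:
            raise ValidationError(f"age must be > 0, got {self.age}")
        if not self.bmi > 0:
            raise ValidationError(f"bmi must be > 0, got {self.bmi}")
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass
class SessionLog:
    """Distinct calendar dates on which a subject completed a session."""

    subject_id: str
    session_dates: set[date] = field(default_factory=set)


@dataclass(frozen=True)
class StudyWindow:
    """A 7-day analysis window in day offsets relative to intervention start.

    ``day_range`` is half-open, so adjacent windows never share a day and a
    sample exactly at the intervention start (offset 0) belongs to week 1.
    """

    label: str
    day_range: tuple[int, int]

    def __post_init__(self):
        lo, hi = self.day_range
        if hi - lo != 7:
            raise ValidationError(
                f"window {self.label!r} spans {hi - lo} days, expected 7"
            )

    def contains(self, day_offset: int) -> bool:
        lo, hi = self.day_range
        return lo <= day_offset < hi


def default_windows() -> list[StudyWindow]:
    """Baseline [-7, 0) plus week1..week7, tiling day offsets [-7, 49)."""
    windows = [StudyWindow("baseline", (-7, 0))]
    windows += [StudyWindow(f"week{k}", (7 * (k - 1), 7 * k)) for k in range(1, 8)]
    return windows


# ---------------------------------------------------------------------------
# CSV I/O


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_hrv(path) -> list[HRVSample]:
    """Read ``hrv_samples.csv`` (subject_id, timestamp, sdnn_ms, window_s).

    Malformed rows (unparseable timestamp, nonpositive SDNN or window) are
    rejected collectively with their 1-based row numbers.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(df, HRV_COLUMNS, path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    sdnn = pd.to_numeric(df["sdnn_ms"], errors="coerce")
    window = pd.to_numeric(df["window_s"], errors="coerce")
    bad = ts.isna() | sdnn.isna() | window.isna() | (sdnn <= 0) | (window <= 0)
    if bad.any():
        raise ValidationError(
            f"{path}: invalid HRV rows", rows=(df.index[bad] + 1).tolist()
        )
    return [
        HRVSample(str(s), pd.Timestamp(t), float(v), float(w))
        for s, t, v, w in zip(df["subject_id"], ts, sdnn, window)
    ]


def write_hrv(samples: Iterable[HRVSample], path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "timestamp": s.timestamp.isoformat(),
                "sdnn_ms": s.sdnn_ms,
                "window_s": s.window_s,
            }
            for s in samples
        ],
        columns=HRV_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_subjects(path) -> list[SubjectProfile]:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(df, SUBJECT_COLUMNS, path)
    start = pd.to_datetime(df["intervention_start"], errors="coerce")
    age = pd.to_numeric(df["age"], errors="coerce")
    bmi = pd.to_numeric(df["bmi"], errors="coerce")
    bad = (
        start.isna()
        | age.isna()
        | bmi.isna()
        | (age <= 0)
        | (bmi <= 0)
        | ~df["sex"].isin(["female", "male"])
    )
    if bad.any():
        raise ValidationError(
            f"{path}: invalid subject rows", rows=(df.index[bad] + 1).tolist()
        )
    return [
        SubjectProfile(str(s), float(a), str(x), float(b), d.date())
        for s, a, x, b, d in zip(df["subject_id"], age, df["sex"], bmi, start)
    ]


def write_subjects(subjects: Iterable[SubjectProfile], path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "bmi": s.bmi,
                "intervention_start": s.intervention_start.isoformat(),
            }
            for s in subjects
        ],
        columns=SUBJECT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_sessions(path) -> list[SessionLog]:
    """Read the long-format session log (subject_id, session_date)."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(df, SESSION_COLUMNS, path)
    dates = pd.to_datetime(df["session_date"], errors="coerce")
    if dates.isna().any():
        raise ValidationError(
            f"{path}: unparseable session dates",
            rows=(df.index[dates.isna()] + 1).tolist(),
        )
    logs: dict[str, SessionLog] = {}
    for sid, d in zip(df["subject_id"], dates):
        logs.setdefault(str(sid), SessionLog(str(sid))).session_dates.add(d.date())
    return list(logs.values())


def write_sessions(logs: Iterable[SessionLog], path) -> None:
    rows = [
        {"subject_id": log.subject_id, "session_date": d.isoformat()}
        for log in logs
        for d in sorted(log.session_dates)
    ]
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Window assignment


def day_offset(timestamp: pd.Timestamp, intervention_start: date) -> int:
    """Calendar-day offset of a sample relative to the intervention start."""
    return (timestamp.date() - intervention_start).days


def assign_windows(
    samples: Iterable[HRVSample],
    profile: SubjectProfile,
    windows: Sequence[StudyWindow] | None = None,
) -> list[tuple[HRVSample, str]]:
    """Label each sample with the study window containing its day offset.

    Windows are half-open and disjoint, so a sample receives at most one
    label; anything outside every window gets :data:`OUT_OF_WINDOW`.
    """
    windows = list(windows) if windows is not None else default_windows()
    out = []
    for s in samples:
        off = day_offset(s.timestamp, profile.intervention_start)
        label = next((w.label for w in windows if w.contains(off)), OUT_OF_WINDOW)
        out.append((s, label))
    return out


# ---------------------------------------------------------------------------
# Compliance


@dataclass(frozen=True)
class ComplianceSummary:
    subject_id: str
    sessions_done: int
    expected: int
    fraction: float
    strata_membership: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "sessions_done": self.sessions_done,
            "expected": self.expected,
            "fraction": self.fraction,
            "strata_membership": dict(self.strata_membership),
        }


def compute_compliance(
    log: SessionLog,
    intervention_start: date | None = None,
    expected: int = EXPECTED_SESSIONS,
) -> ComplianceSummary:
    """Fraction of the 35 prescribed sessions completed, with strata flags.

    Distinct dates only — two sessions on one day count once.  When the
    intervention start is given, dates outside the 35-day window are
    ignored; otherwise all logged dates count.

    Strata: ``>0%`` means at least one session (strict), ``>=20%`` and
    ``>=50%`` are inclusive thresholds on the completed fraction, so the
    strata are nested.
    """
    dates = set(log.session_dates)
    if intervention_start is not None:
        lo = intervention_start
        hi = intervention_start + timedelta(days=expected)
        dates = {d for d in dates if lo <= d < hi}
    done = len(dates)
    fraction = done / expected
    membership = {
        ">0%": done > 0,
        ">=20%": fraction >= 0.20,
        ">=50%": fraction >= 0.50,
    }
    return ComplianceSummary(log.subject_id, done, expected, fraction, membership)


def format_percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places (72/127 -> 56.7)."""
    if total <= 0:
        raise ValidationError(f"total must be positive, got {total}")
    pct = decimal.Decimal(count) / decimal.Decimal(total) * 100
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=decimal.ROUND_HALF_UP))


def stratify(
    summaries: Iterable[ComplianceSummary], n_consented: int
) -> pd.DataFrame:
    """Per-stratum rosters, counts, and percentages of the consented N.

    ``n_consented`` is supplied explicitly because consented subjects
    without any session log still belong in the denominator.
    """
    summaries = list(summaries)
    rows = []
    for stratum in STRATA:
        members = sorted(
            s.subject_id for s in summaries if s.strata_membership[stratum]
        )
        if len(members) > n_consented:
            raise ValidationError(
                f"stratum {stratum} has {len(members)} members but only "
                f"{n_consented} consented subjects"
            )
        rows.append(
            {
                "stratum": stratum,
                "count": len(members),
                "percent": format_percent(len(members), n_consented),
                "subject_ids": members,
            }
        )
    return pd.DataFrame(rows)
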