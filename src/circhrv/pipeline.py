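"""End-to-end study analysis: simulate/load -> compliance -> cosinor ->
bootstrap contrasts -> survey analysis, with a reproducible manifest.

Each compliance stratum (>0%, >=20%, >=50%) is analysed independently —
the model is refitted on the stratum's subjects, so variance components
are not shared across strata — and three table files are written:

* ``table1_demographics.csv`` — stratum rosters, counts, percentages of
  the consented N, and summary demographics;
* ``table2_surveys.csv`` — per-instrument per-timepoint means (SD) and
  change-from-baseline p-values per stratum;
* ``table3_circadian.csv`` — per-window (MESOR, amplitude, acrophase)
  with bootstrap CIs, baseline differences, and p-values per stratum.

``manifest.json`` records the config hash, seed, package versions,
per-stage timings and a SHA-256 per output file.  Identical config and
seed give byte-identical table files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cosinor import FitOptions
from .data_model import (
    STRATA,
    SessionLog,
    compute_compliance,
    format_percent,
    read_hrv,
    read_sessions,
    read_subjects,
    stratify,
)
from .inference import BootstrapConfig, bootstrap_fit, comparison_table
from .surveys import longitudinal_change
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_study_analysis"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full study-analysis run.

    Either ``input_dir`` (subjects.csv / hrv_samples.csv / sessions.csv /
    surveys.csv as written by the simulator) or ``cohort`` (simulate
    in-process) supplies the data.  ``seed`` drives every stochastic stage
    through a spawned seed sequence.
    """

    out_dir: str = "results/run"
    seed: int = 0
    cohort: CohortConfig | None = None
    input_dir: str | None = None
    fit_options: FitOptions = field(default_factory=FitOptions)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    significance_level: float = 0.05  # two-sided, reported only

    def validate(self) -> None:
        if self.cohort is None and self.input_dir is None:
            raise PipelineError("config: either 'cohort' or 'input_dir' is required")
        if not (0 < self.significance_level < 1):
            raise PipelineError(
                f"config: significance_level must be in (0, 1), got "
                f"{self.significance_level}"
            )


def _config_hash(cfg: RunConfig) -> str:
    def default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return str(obj)

    blob = json.dumps(dataclasses.asdict(cfg), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: RunConfig, seed: int):
    if cfg.input_dir is not None:
        d = Path(cfg.input_dir)
        subjects = read_subjects(d / "subjects.csv")
        hrv = read_hrv(d / "hrv_samples.csv")
        sessions = read_sessions(d / "sessions.csv")
        surveys_df = pd.read_csv(d / "surveys.csv", dtype={"subject_id": str})
        return subjects, hrv, sessions, surveys_df
    cohort_cfg = dataclasses.replace(cfg.cohort, seed=seed)
    cohort = generate_cohort(cohort_cfg)
    survey_rows = [
        {
            "subject_id": r.subject_id,
            "timepoint": r.timepoint,
            "instrument": r.instrument,
            "item_index": i,
            "response": v,
        }
        for r in cohort.surveys
        for i, v in enumerate(r.items, start=1)
    ]
    return (
        cohort.subjects,
        cohort.hrv_df,
        cohort.compliance,
        pd.DataFrame(survey_rows),
    )


def _surveys_long_to_scores(surveys_df: pd.DataFrame) -> pd.DataFrame:
    from .surveys import SurveyResponse, score_frame

    responses = []
    grouped = surveys_df.sort_values("item_index").groupby(
        ["subject_id", "timepoint", "instrument"], sort=True
    )
    for (sid, tp, inst), grp in grouped:
        responses.append(
            SurveyResponse(str(sid), tp, inst, tuple(int(v) for v in grp["response"]))
        )
    return score_frame(responses)


def run_study_analysis(cfg: RunConfig) -> dict:
    """Execute every stage per stratum and write the result bundle.

    Returns the manifest dict.  Any stage failure raises
    :class:`PipelineError` naming the stage; outputs written before the
    failure are preserved.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(2)
    sim_seed = int(seeds[0].generate_state(1)[0] % 2**31)
    boot_seed = int(seeds[1].generate_state(1)[0] % 2**31)

    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": _versions(),
        "stages": {},
        "files": {},
    }
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return _Timer()

    with stage("load_or_simulate"):
        subjects, hrv, sessions, surveys_df = _load_inputs(cfg, sim_seed)
        profiles = {s.subject_id: s for s in subjects}

    with stage("compliance"):
        summaries = [
            compute_compliance(log, profiles[log.subject_id].intervention_start)
            for log in sessions
            if log.subject_id in profiles
        ]
        logged = {s.subject_id for s in summaries}
        summaries += [
            compute_compliance(SessionLog(sid), profiles[sid].intervention_start)
            for sid in profiles
            if sid not in logged
        ]
        strata_df = stratify(summaries, n_consented=len(subjects))
        table1 = _demographics_table(subjects, strata_df)
        table1.to_csv(out / "table1_demographics.csv", index=False)

    rosters = dict(zip(strata_df["stratum"], strata_df["subject_ids"]))

    with stage("surveys"):
        scores = _surveys_long_to_scores(surveys_df)
        t2_parts = []
        for stratum in STRATA:
            part = longitudinal_change(scores, rosters[stratum])
            part.insert(0, "stratum", stratum)
            t2_parts.append(part)
        table2 = pd.concat(t2_parts, ignore_index=True)
        table2.to_csv(out / "table2_surveys.csv", index=False)

    with stage("cosinor_bootstrap"):
        t3_parts = []
        for stratum in STRATA:
            roster = set(rosters[stratum])
            stratum_subjects = [s for s in subjects if s.subject_id in roster]
            if len(stratum_subjects) < 2:
                logger.warning("stratum %s has < 2 subjects; skipped", stratum)
                continue
            boot = bootstrap_fit(
                _subset_hrv(hrv, roster),
                stratum_subjects,
                fit_options=cfg.fit_options,
                cfg=dataclasses.replace(cfg.bootstrap, seed=boot_seed),
            )
            part = comparison_table(boot)
            part.insert(0, "stratum", stratum)
            part["n_subjects"] = boot.fit.n_subjects
            part["n_boot_used"] = boot.n_boot_used
            t3_parts.append(part)
        table3 = pd.concat(t3_parts, ignore_index=True)
        table3.to_csv(out / "table3_circadian.csv", index=False)

    manifest["stages"] = timings
    for f in sorted(out.glob("*.csv")):
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _subset_hrv(hrv, roster: set[str]):
    if isinstance(hrv, pd.DataFrame):
        return hrv[hrv["subject_id"].isin(roster)]
    return [s for s in hrv if s.subject_id in roster]


def _demographics_table(subjects, strata_df: pd.DataFrame) -> pd.DataFrame:
    by_id = {s.subject_id: s for s in subjects}
    rows = [
        {
            "stratum": "consented",
            "n": len(subjects),
            "percent": 100.0,
            **_demo_summary(subjects),
        }
    ]
    for _, r in strata_df.iterrows():
        members = [by_id[sid] for sid in r["subject_ids"]]
        rows.append(
            {
                "stratum": r["stratum"],
                "n": r["count"],
                "percent": r["percent"],
                **_demo_summary(members),
            }
        )
    return pd.DataFrame(rows)


def _demo_summary(members) -> dict:
    if not members:
        return {
            "age_mean": np.nan, "age_sd": np.nan, "male_n": 0,
            "male_pct": np.nan, "bmi_mean": np.nan, "bmi_sd": np.nan,
        }
    ages = np.array([m.age for m in members])
    bmis = np.array([m.bmi for m in members])
    male = sum(m.sex == "male" for m in members)
    return {
        "age_mean": round(float(ages.mean()), 1),
        "age_sd": round(float(ages.std(ddof=1)), 1) if len(ages) > 1 else np.nan,
        "male_n": int(male),
        "male_pct": format_percent(male, len(members)),
        "bmi_mean": round(float(bmis.mean()), 1),
        "bmi_sd": round(float(bmis.std(ddof=1)), 1) if len(bmis) > 1 else np.nan,
    }


def _versions() -> dict:
    import sys

    import scipy
    import statsmodels

    return {
        "circhrv": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
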