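#!/usr/bin/env python
"""Stratify the cohort by biofeedback compliance.

Reads the simulated cohort (generating it first if needed), computes each
subject's fraction of the 35 prescribed sessions, stratifies at >0%,
>=20% and >=50%, and writes the demographics table to
results/table1_demographics.csv.

Run from the repository root:  python analysis/02_compliance_stratification.py
"""

import runpy
from pathlib import Path

import pandas as pd

from circhrv.data_model import compute_compliance, read_sessions, read_subjects, stratify
from circhrv.pipeline import _demographics_table

COHORT = Path("scratch/cohort")
OUT = Path("results/table1_demographics.csv")


def main() -> None:
    if not (COHORT / "subjects.csv").exists():
        runpy.run_path("analysis/01_simulate_cohort.py", run_name="__main__")
    subjects = read_subjects(COHORT / "subjects.csv")
    by_id = {s.subject_id: s for s in subjects}
    logs = {log.subject_id: log for log in read_sessions(COHORT / "sessions.csv")}
    from circhrv.data_model import SessionLog

    summaries = [
        compute_compliance(
            logs.get(sid, SessionLog(sid)), by_id[sid].intervention_start
        )
        for sid in by_id
    ]
    strata = stratify(summaries, n_consented=len(subjects))
    table1 = _demographics_table(subjects, strata)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    table1.to_csv(OUT, index=False)
    print(table1.to_string(index=False))
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
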