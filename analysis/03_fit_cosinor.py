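#!/usr/bin/env python
"""Fit the mixed-effect cosinor model per compliance stratum.

For each stratum the joint model (window factor x cosinor terms, age/sex/
BMI on the MESOR, per-subject random effects) is fitted to the stratum's
SDNN stream; the derived weekly (MESOR, amplitude, acrophase) land in
results/cosinor_window_params.csv.

Run from the repository root:  python analysis/03_fit_cosinor.py
"""

import runpy
from pathlib import Path

import pandas as pd

from circhrv.cosinor import FitOptions, fit_mixed_cosinor
from circhrv.data_model import (
    STRATA,
    SessionLog,
    compute_compliance,
    read_hrv,
    read_sessions,
    read_subjects,
    stratify,
)

COHORT = Path("scratch/cohort")
OUT = Path("results/cosinor_window_params.csv")


def main() -> None:
    if not (COHORT / "subjects.csv").exists():
        runpy.run_path("analysis/01_simulate_cohort.py", run_name="__main__")
    subjects = read_subjects(COHORT / "subjects.csv")
    hrv = read_hrv(COHORT / "hrv_samples.csv")
    by_id = {s.subject_id: s for s in subjects}
    logs = {log.subject_id: log for log in read_sessions(COHORT / "sessions.csv")}
    summaries = [
        compute_compliance(logs.get(sid, SessionLog(sid)), by_id[sid].intervention_start)
        for sid in by_id
    ]
    strata = stratify(summaries, n_consented=len(subjects))
    rosters = dict(zip(strata["stratum"], strata["subject_ids"]))

    rows = []
    for stratum in STRATA:
        roster = set(rosters[stratum])
        fit = fit_mixed_cosinor(
            [s for s in hrv if s.subject_id in roster],
            [s for s in subjects if s.subject_id in roster],
            options=FitOptions(re_structure="intercept"),
        )
        print(f"{stratum}: n={fit.n_subjects} subjects, {fit.n_samples} samples, "
              f"engine={fit.engine}, converged={fit.converged}")
        for w in fit.window_labels:
            p = fit.window_params[w]
            rows.append(
                {
                    "stratum": stratum, "window": w,
                    "mesor_ms": round(p.mesor, 2),
                    "amplitude_ms": round(p.amplitude, 2),
                    "acrophase_rad": round(p.acrophase, 3),
                }
            )
    out = pd.DataFrame(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(OUT, index=False)
    print(out.to_string(index=False))
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
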