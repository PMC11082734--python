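"""Synthetic cohort generator: determinism, sampling statistics, truth
bookkeeping, compliance mixture realism, and survey trajectories."""

import numpy as np
import pandas as pd
import pytest

from circhrv.cosinor import CircadianParams, cosinor_predict
from circhrv.surveys import INSTRUMENTS, score
from circhrv.synthetic import (
    DEFAULT_COMPLIANCE_MIXTURE,
    CohortConfig,
    ComplianceStratum,
    ConfigurationError,
    generate_cohort,
    generate_survey_trajectories,
    write_cohort,
)

FULL_COMPLIANCE = (ComplianceStratum("full", 1.0, 1.0),)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_subjects", 0),
            ("female_fraction", 1.5),
            ("night_bias_weight", -0.1),
            ("sdnn_floor", 300.0),
            ("residual_sd", -1.0),
            ("samples_per_day_mean", 0.0),
            ("samples_per_day_dispersion", -2.0),
            ("count_distribution", "geometric"),
            ("n_observation_weeks", 0),
        ],
    )
    def test_invalid_field_named(self, field, value):
        cfg = CohortConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            cfg.validate()

    def test_mixture_must_sum_to_one(self):
        cfg = CohortConfig(
            compliance_mixture=(
                ComplianceStratum("a", 0.5, 0.1),
                ComplianceStratum("b", 0.4, 0.5),
            )
        )
        with pytest.raises(ConfigurationError, match="sum to 1"):
            cfg.validate()


class TestGeneration:
    def test_noiseless_degenerate_cohort_is_constant(self):
        cfg = CohortConfig(
            n_subjects=3,
            residual_sd=0.0,
            random_effect_sds=(0.0, 0.0, 0.0),
            baseline_params=CircadianParams(50.0, 0.0, 0.0),
            intervention_mesor_shift=0.0,
            seed=7,
        )
        cohort = generate_cohort(cfg)
        assert np.allclose(cohort.hrv_df["sdnn_ms"], 50.0)

    def test_same_seed_identical_output(self, tmp_path):
        a = generate_cohort(CohortConfig(n_subjects=10, seed=5))
        b = generate_cohort(CohortConfig(n_subjects=10, seed=5))
        pd.testing.assert_frame_equal(a.hrv_df, b.hrv_df)
        assert a.subjects == b.subjects
        assert a.surveys == b.surveys
        assert [sorted(l.session_dates) for l in a.compliance] == [
            sorted(l.session_dates) for l in b.compliance
        ]
        # byte-identical after serialization
        pa = write_cohort(a, tmp_path / "a")
        pb = write_cohort(b, tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_subjects=5, seed=1))
        b = generate_cohort(CohortConfig(n_subjects=5, seed=2))
        assert not a.hrv_df["sdnn_ms"].equals(b.hrv_df["sdnn_ms"])

    def test_samples_per_day_matches_target(self):
        cfg = CohortConfig(n_subjects=200, seed=11)
        cohort = generate_cohort(cfg)
        n_days = 7 * (1 + cfg.n_observation_weeks)
        counts = (
            cohort.hrv_df.groupby("subject_id").size().reindex(
                [s.subject_id for s in cohort.subjects], fill_value=0
            )
            / n_days
        )
        mean = counts.mean()
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 4.7) < 3 * se
        # dispersion emulates the reported SD 3.5 of daily counts
        daily = cohort.hrv_df.assign(
            day=cohort.hrv_df["timestamp"].dt.floor("D")
        ).groupby(["subject_id", "day"]).size()
        assert daily.std(ddof=1) == pytest.approx(3.5, abs=0.6)

    def test_values_clipped_to_device_range(self):
        cfg = CohortConfig(
            n_subjects=20, residual_sd=500.0, sdnn_floor=10.0,
            sdnn_ceiling=200.0, seed=3,
        )
        v = generate_cohort(cfg).hrv_df["sdnn_ms"]
        assert v.min() >= 10.0 and v.max() <= 200.0
        assert (v == 10.0).any() and (v == 200.0).any()  # truncation visible

    def test_night_bias(self):
        cfg = CohortConfig(n_subjects=50, night_bias_weight=0.5, seed=9)
        hours = generate_cohort(cfg).hrv_df["timestamp"].dt.hour
        night_frac = (hours < 6).mean()
        # 50% forced night + 25% of the uniform remainder = 62.5%
        assert night_frac == pytest.approx(0.625, abs=0.03)

    def test_truth_is_period_average_of_generator(self):
        cfg = CohortConfig(n_subjects=4, seed=13, compliance_mixture=FULL_COMPLIANCE)
        cohort = generate_cohort(cfg)
        grid = np.linspace(0, 24, 4801)[:-1]
        for sid, per_window in cohort.truth.items():
            for label, p in per_window.items():
                assert cosinor_predict(p, grid).mean() == pytest.approx(
                    p.mesor, abs=1e-9
                )

    def test_truth_contains_shift_for_adherent_weeks(self):
        cfg = CohortConfig(
            n_subjects=3, seed=17, compliance_mixture=FULL_COMPLIANCE,
            intervention_mesor_shift=5.0,
        )
        cohort = generate_cohort(cfg)
        for per_window in cohort.truth.values():
            base = per_window["baseline"].mesor
            for w in ("week1", "week2", "week3", "week4", "week5"):
                assert per_window[w].mesor == pytest.approx(base + 5.0)
            for w in ("week6", "week7"):
                assert per_window[w].mesor == pytest.approx(base)

    def test_compliance_mixture_matches_reported_strata(self):
        cohort = generate_cohort(CohortConfig(n_subjects=127, seed=19))
        from circhrv.data_model import compute_compliance

        fractions = {">0%": 72 / 127, ">=20%": 49 / 127, ">=50%": 21 / 127}
        summaries = [
            compute_compliance(log, cohort.subjects[0].intervention_start)
            for log in cohort.compliance
        ]
        for stratum, frac in fractions.items():
            realized = sum(s.strata_membership[stratum] for s in summaries)
            expected = 127 * frac
            se = np.sqrt(127 * frac * (1 - frac))
            assert abs(realized - expected) <= 3 * se

    def test_every_sample_belongs_to_a_subject(self):
        cohort = generate_cohort(CohortConfig(n_subjects=8, seed=23))
        ids = {s.subject_id for s in cohort.subjects}
        assert set(cohort.hrv_df["subject_id"]) <= ids
        assert set(cohort.truth) == ids


class TestSurveyTrajectories:
    def _subjects(self, n):
        from datetime import date

        from circhrv.data_model import SubjectProfile

        return [
            SubjectProfile(f"s{i}", 35.0, "female", 24.0, date(2021, 9, 1))
            for i in range(n)
        ]

    def test_zero_shift_zero_noise_minimum_items(self):
        responses = generate_survey_trajectories(
            self._subjects(2),
            effect_profile={},
            seed=0,
            baseline_item_means={"phq4": 0.0},
            noise_sd=0.0,
        )
        phq = [r for r in responses if r.instrument == "phq4"]
        assert len(phq) == 8  # 2 subjects x 4 timepoints
        assert all(score(r).total == 0 for r in phq)

    def test_configured_pss10_drop_recovered(self):
        n = 1000
        responses = generate_survey_trajectories(
            self._subjects(n),
            effect_profile={"pss10": {"week17": -1.0}},  # -10 points total
            seed=1,
            baseline_item_means={"pss10": 2.0},
            noise_sd=0.5,
        )
        totals = {
            tp: np.array(
                [score(r).total for r in responses
                 if r.instrument == "pss10" and r.timepoint == tp]
            )
            for tp in ("baseline", "week17")
        }
        drop = totals["baseline"].mean() - totals["week17"].mean()
        se = np.sqrt(
            totals["baseline"].var(ddof=1) / n + totals["week17"].var(ddof=1) / n
        )
        assert abs(drop - 10.0) < 3 * se

    def test_generated_responses_always_scoreable(self):
        responses = generate_survey_trajectories(self._subjects(20), seed=2)
        for r in responses:
            spec = INSTRUMENTS[r.instrument]
            lo, hi = spec.total_range
            assert lo <= score(r).total <= hi

    def test_missingness_drops_whole_timepoints(self):
        responses = generate_survey_trajectories(
            self._subjects(50), seed=3, missing_prob={"week17": 1.0}
        )
        assert not any(r.timepoint == "week17" for r in responses)
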