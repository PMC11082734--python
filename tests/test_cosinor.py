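"""Cosinor algebra, single-rhythm fits, and the mixed-effect model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from circhrv.cosinor import (
    CircadianParams,
    FitError,
    FitOptions,
    LinearCosinorCoefs,
    coefs_to_params,
    cosinor_predict,
    fit_mixed_cosinor,
    fit_single_cosinor,
    params_to_coefs,
    time_to_angle,
    wrap_acrophase,
)


class TestAngles:
    @pytest.mark.parametrize(
        "t,expected",
        [(0, (1, 0)), (6, (0, 1)), (12, (-1, 0)), (18, (0, -1)), (24, (1, 0))],
    )
    def test_cardinal_times(self, t, expected):
        x, z = time_to_angle(t)
        assert (x, z) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-100, 100), st.floats(0.1, 100))
    def test_unit_circle(self, t, period):
        x, z = time_to_angle(t, period)
        assert x**2 + z**2 == pytest.approx(1.0)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            time_to_angle(3.0, 0.0)


class TestPredict:
    def test_flat_rhythm(self):
        p = CircadianParams(50.0, 0.0, 0.0)
        assert np.allclose(cosinor_predict(p, np.linspace(0, 24, 9)), 50.0)

    def test_peak_at_phase_zero(self):
        assert cosinor_predict(CircadianParams(50, 5, 0.0), 0.0) == pytest.approx(55.0)

    def test_peak_shifted_to_0600(self):
        p = CircadianParams(50, 5, -np.pi / 2)
        assert cosinor_predict(p, 6.0) == pytest.approx(55.0)
        assert p.peak_time == pytest.approx(6.0)


params_strategy = st.tuples(
    st.floats(-100, 100),  # mesor
    st.floats(1e-6, 50),  # amplitude > 0
    st.floats(-2 * np.pi + 1e-9, 0),  # acrophase in stored branch
)


class TestCoefAlgebra:
    def test_simple_forward(self):
        c = params_to_coefs(CircadianParams(0.0, 1.0, 0.0))
        assert (c.beta, c.gamma) == pytest.approx((1.0, 0.0))
        p = coefs_to_params(c)
        assert (p.amplitude, p.acrophase) == pytest.approx((1.0, 0.0))

    def test_quarter_phase_branch(self):
        p = coefs_to_params(LinearCosinorCoefs(0.0, 0.0, -1.0))
        assert p.amplitude == pytest.approx(1.0)
        assert p.acrophase == pytest.approx(-3 * np.pi / 2)

    def test_zero_amplitude_degenerate(self):
        p = coefs_to_params(LinearCosinorCoefs(38.0, 0.0, 0.0))
        assert p.degenerate and p.acrophase == 0.0

    @given(params_strategy)
    def test_round_trip_identity(self, tup):
        m, a, phi = tup
        p = CircadianParams(m, a, phi)
        q = coefs_to_params(params_to_coefs(p))
        assert q.mesor == pytest.approx(m, abs=1e-12)
        assert q.amplitude == pytest.approx(a, rel=1e-12, abs=1e-12)
        # phases compare modulo 2*pi
        d = (q.acrophase - phi) % (2 * np.pi)
        assert min(d, 2 * np.pi - d) == pytest.approx(0.0, abs=1e-9)

    @given(params_strategy, st.floats(-50, 50))
    def test_predictions_invariant_to_phase_branch(self, tup, t):
        m, a, phi = tup
        p1 = CircadianParams(m, a, phi)
        shifted = wrap_acrophase(phi + 2 * np.pi)
        p2 = CircadianParams(m, a, shifted)
        assert cosinor_predict(p1, t) == pytest.approx(cosinor_predict(p2, t))


class TestSingleFit:
    def test_noiseless_exact_recovery(self):
        t = np.arange(8) * 3.0
        truth = CircadianParams(50.0, 5.0, -2.0)
        p, _ = fit_single_cosinor(t, cosinor_predict(truth, t))
        assert p.mesor == pytest.approx(50.0, abs=1e-9)
        assert p.amplitude == pytest.approx(5.0, abs=1e-9)
        assert p.acrophase == pytest.approx(-2.0, abs=1e-9)

    def test_matches_nonlinear_least_squares_oracle(self, rng):
        t = rng.uniform(0, 24, 100)
        truth = CircadianParams(50.0, 5.0, -2.0)
        y = cosinor_predict(truth, t) + rng.normal(0, 5, 100)
        p, _ = fit_single_cosinor(t, y)

        def model(t, m, a, phi):
            return m + a * np.cos(2 * np.pi * t / 24 + phi)

        (m, a, phi), _ = curve_fit(model, t, y, p0=(40.0, 3.0, -1.5))
        if a < 0:  # normalize the oracle's sign/phase ambiguity
            a, phi = -a, phi + np.pi
        assert p.mesor == pytest.approx(m, abs=1e-6)
        assert p.amplitude == pytest.approx(a, abs=1e-6)
        d = (p.acrophase - phi) % (2 * np.pi)
        assert min(d, 2 * np.pi - d) == pytest.approx(0.0, abs=1e-6)

    def test_constant_input_is_degenerate(self):
        t = np.arange(10) * 2.4
        p, _ = fit_single_cosinor(t, np.full(10, 38.0))
        assert p.mesor == pytest.approx(38.0)
        assert p.degenerate

    def test_single_clock_time_rank_deficient(self):
        with pytest.raises(FitError, match="clock times"):
            fit_single_cosinor(np.full(10, 8.0), np.arange(10.0))

    def test_too_few_samples(self):
        with pytest.raises(FitError):
            fit_single_cosinor(np.array([0.0, 6.0, 12.0]), np.zeros(3))

    def test_mesor_is_period_average_of_fitted_curve(self, rng):
        t = rng.uniform(0, 24, 60)
        y = cosinor_predict(CircadianParams(45, 6, -1.2), t) + rng.normal(0, 3, 60)
        p, _ = fit_single_cosinor(t, y)
        grid = np.linspace(0, 24, 20001)[:-1]
        assert cosinor_predict(p, grid).mean() == pytest.approx(p.mesor, abs=1e-6)

    def test_time_shift_covariance(self, rng):
        t = rng.uniform(0, 24, 80)
        y = cosinor_predict(CircadianParams(50, 5, -2.0), t) + rng.normal(0, 2, 80)
        p0, _ = fit_single_cosinor(t, y)
        delta = 3.0
        p1, _ = fit_single_cosinor(t + delta, y)
        assert p1.mesor == pytest.approx(p0.mesor, abs=1e-8)
        assert p1.amplitude == pytest.approx(p0.amplitude, abs=1e-8)
        expected = (p0.acrophase - 2 * np.pi * delta / 24) % (2 * np.pi)
        assert p1.acrophase % (2 * np.pi) == pytest.approx(expected, abs=1e-8)


def _frame_to_inputs(cohort):
    return cohort.hrv_df, cohort.subjects


class TestMixedFit:
    def test_single_subject_reduces_to_per_window_ols(self, rng):
        from circhrv.data_model import SubjectProfile
        from datetime import date

        start = date(2021, 9, 1)
        profile = SubjectProfile("solo", 40.0, "male", 25.0, start)
        rows = []
        truth = {"baseline": CircadianParams(48, 4, -2.5),
                 "week1": CircadianParams(53, 4, -2.5)}
        for day0, label in [(-7, "baseline"), (0, "week1")]:
            for d in range(7):
                t = rng.uniform(0, 24, 6)
                y = cosinor_predict(truth[label], t) + rng.normal(0, 3, 6)
                for ti, yi in zip(t, y):
                    rows.append(
                        {
                            "subject_id": "solo",
                            "timestamp": pd.Timestamp(start)
                            + pd.Timedelta(days=day0 + d, hours=float(ti)),
                            "sdnn_ms": yi,
                        }
                    )
        df = pd.DataFrame(rows)
        fit = fit_mixed_cosinor(
            df, [profile], options=FitOptions(re_structure="none")
        )
        from circhrv.cosinor import hours_of_day

        for label in ("baseline", "week1"):
            mask = [
                (pd.Timestamp(r.timestamp).date() - start).days in
                (range(-7, 0) if label == "baseline" else range(0, 7))
                for r in df.itertuples()
            ]
            sub = df[mask]
            p_ols, _ = fit_single_cosinor(
                hours_of_day(sub["timestamp"]), sub["sdnn_ms"].to_numpy()
            )
            p_joint = fit.window_params[label]
            assert p_joint.mesor == pytest.approx(p_ols.mesor, abs=1e-8)
            assert p_joint.amplitude == pytest.approx(p_ols.amplitude, abs=1e-8)
            assert p_joint.acrophase == pytest.approx(p_ols.acrophase, abs=1e-8)

    def test_constant_offset_equivariance(self, small_cohort):
        opts = FitOptions(re_structure="intercept")
        fit0 = fit_mixed_cosinor(small_cohort.hrv_df, small_cohort.subjects, options=opts)
        shifted = small_cohort.hrv_df.copy()
        shifted["sdnn_ms"] = shifted["sdnn_ms"] + 10.0
        fit1 = fit_mixed_cosinor(shifted, small_cohort.subjects, options=opts)
        for w in fit0.window_labels:
            assert fit1.window_params[w].mesor == pytest.approx(
                fit0.window_params[w].mesor + 10.0, abs=1e-6
            )
            assert fit1.window_params[w].amplitude == pytest.approx(
                fit0.window_params[w].amplitude, abs=1e-6
            )
            assert fit1.window_params[w].acrophase == pytest.approx(
                fit0.window_params[w].acrophase, abs=1e-6
            )

    def test_fast_reml_matches_statsmodels_mixedlm(self, small_cohort):
        import statsmodels.api as sm

        from circhrv.cosinor import build_design, samples_to_frame

        fit = fit_mixed_cosinor(
            small_cohort.hrv_df,
            small_cohort.subjects,
            options=FitOptions(re_structure="intercept"),
        )
        df = samples_to_frame(small_cohort.hrv_df, small_cohort.subjects)
        X, y, names, _, _ = build_design(df, FitOptions())
        res = sm.MixedLM(y, X, groups=df["subject_id"].to_numpy()).fit(reml=True)
        assert np.allclose(fit.coef.to_numpy(), np.asarray(res.fe_params), atol=1e-4)
        assert fit.resid_var == pytest.approx(float(res.scale), rel=1e-3)
        assert fit.re_cov[0, 0] == pytest.approx(
            float(np.asarray(res.cov_re)[0, 0]), rel=1e-2
        )

    def test_full_random_effects_engine_recovers_shift(self, small_cohort):
        fit = fit_mixed_cosinor(
            small_cohort.hrv_df,
            small_cohort.subjects,
            options=FitOptions(re_structure="intercept_xz"),
        )
        assert fit.engine in ("intercept_xz", "intercept")
        base = fit.window_params["baseline"].mesor
        # +5 ms generated in weeks 2-4 of this cohort
        for w in ("week2", "week3", "week4"):
            assert fit.window_params[w].mesor - base == pytest.approx(5.0, abs=2.5)
        if fit.engine == "intercept_xz":
            assert fit.re_cov.shape == (3, 3)
            assert np.all(np.linalg.eigvalsh(fit.re_cov) > -1e-8)

    def test_two_subjects_required(self, small_cohort):
        one = small_cohort.hrv_df[
            small_cohort.hrv_df["subject_id"] == small_cohort.subjects[0].subject_id
        ]
        with pytest.raises(FitError, match="2 subjects"):
            fit_mixed_cosinor(one, small_cohort.subjects[:1])
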