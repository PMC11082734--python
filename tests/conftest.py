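import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fully compliant cohort with a known +5 ms MESOR shift in
    weeks 2-4; shared by fit/bootstrap tests."""
    from circhrv.cosinor import CircadianParams
    from circhrv.synthetic import CohortConfig, ComplianceStratum, generate_cohort

    cfg = CohortConfig(
        n_subjects=20,
        baseline_params=CircadianParams(50.0, 5.0, -2.9),
        random_effect_sds=(8.0, 1.5, 0.3),
        residual_sd=10.0,
        intervention_mesor_shift=5.0,
        shift_windows=("week2", "week3", "week4"),
        compliance_mixture=(ComplianceStratum("full", 1.0, 1.0),),
        seed=42,
    )
    return generate_cohort(cfg)
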