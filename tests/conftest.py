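import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_cohort():
    from pcosmet import reference_flow_cohort

    return reference_flow_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic 300-patient cohort with planted truth, shared across tests."""
    from pcosmet import GeneratorConfig, generate_cohort

    cohort, truth = generate_cohort(GeneratorConfig(n=300, seed=42))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
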