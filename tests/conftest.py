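import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient cohort with the default planted signal (shared, read-only)."""
    from milsurv.synthetic import SyntheticConfig, generate_cohort

    return generate_cohort(SyntheticConfig(n_patients=60, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
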