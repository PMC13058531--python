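import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from sepsiseval import CohortConfig, generate_score_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A signal-bearing 300-stay score cohort shared by read-only tests."""
    return generate_score_cohort(CohortConfig(n_stays=300, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
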