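import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from habitdyn.synthetic import default_config, generate_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic cohort for fast pipeline tests."""
    cfg = default_config("study1", n_participants=10)
    return generate_study(cfg, seed=123)


@pytest.fixture(scope="session")
def study2():
    """The full-size 75-participant synthetic cohort."""
    return generate_study(default_config("study2"), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
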