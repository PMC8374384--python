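import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trainability import synthetic
from trainability.incremental_test import StepProtocol

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profile() -> synthetic.SubjectProfile:
    """Deterministic typical male subject."""
    return synthetic.default_profile()


@pytest.fixture(scope="session")
def protocol() -> StepProtocol:
    return StepProtocol()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
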