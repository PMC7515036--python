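import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def example_series():
    """Six points realising the worked example's ordinal structure."""
    return np.array([6.0, 3.0, 1.0, 5.0, 2.0, 4.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20190547)
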