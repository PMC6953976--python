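import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netsi import Epidemic

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ep_path3():
    """Minimal epidemic: path transmission 1 -> 2 -> 3."""
    return Epidemic(np.array([0.0, 1.0, 2.5]), {2: 1, 3: 2})


@pytest.fixture
def ep_star3():
    """Star transmission: 1 infects both 2 and 3."""
    return Epidemic(np.array([0.0, 1.2, 3.4]), {2: 1, 3: 1})
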