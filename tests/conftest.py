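import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brainmech.constitutive import DRY_BRAIN, simulate_uniaxial

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth():
    """The calibrated dry-brain constant set."""
    return DRY_BRAIN


@pytest.fixture(scope="session")
def curve_250(truth):
    """Noise-free material-point response at 250 1/s to 30% strain."""
    return simulate_uniaxial(250.0, 0.30, consts=truth, n_output=300)


@pytest.fixture(scope="session")
def curve_50(truth):
    """Noise-free material-point response at 50 1/s to 30% strain."""
    return simulate_uniaxial(50.0, 0.30, consts=truth, n_output=300)
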