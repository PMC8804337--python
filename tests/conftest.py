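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


@pytest.fixture(scope="session")
def coarse_grid():
    """5 nm analysis grid spanning the instrument range."""
    return np.arange(450.0, 1000.5, 5.0)


@pytest.fixture(scope="session")
def reference_basis(coarse_grid):
    from sfdphantom import make_reference_basis

    return make_reference_basis(coarse_grid, include_gelatin_defaults=True)


@pytest.fixture(scope="session")
def inverter():
    from sfdphantom import SFDInverter

    return SFDInverter().fit()
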