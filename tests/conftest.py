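import numpy as np
import pytest

from hostpatch import DecayParams, GrowthParams, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def standard_decay():
    """The standard decay parameterization: delta_K = delta_s = 0.1."""
    return DecayParams(delta_K=0.1, delta_s=0.1)


@pytest.fixture
def standard_growth():
    """Standard growth at full capacity: c = 0.15, K = 10^4."""
    return GrowthParams(c=0.15, K=10_000)


@pytest.fixture
def scaled_params():
    """Desk-scale metapopulation: M=20, K=10^3, tau=200, defaults otherwise."""
    return SimulationParams(M=20, K=1000, tau=200)


@pytest.fixture
def tiny_params():
    """Very small configuration for fast structural tests."""
    return SimulationParams(M=5, K=60, D=10, H0=5, b=2, tau=20, N0=5)
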