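import numpy as np
import pytest

from swinreg.network import MultiStageAffineNetwork, NetworkConfig
from swinreg.synthetic import generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom32():
    """Small phantom shared by tests that only need a realistic volume."""
    return generate_phantom(11, shape=(32, 32, 32), n_structures=6)


@pytest.fixture(scope="session")
def smooth_volume():
    """A smooth strictly-positive 3-D test pattern (no label structure)."""
    x, y, z = np.meshgrid(*[np.linspace(-1, 1, 24)] * 3, indexing="ij")
    v = np.exp(-(x ** 2 + 1.3 * y ** 2 + 0.8 * z ** 2) * 2.0)
    return 0.1 + 0.9 * v / v.max()


@pytest.fixture
def tiny_network():
    return MultiStageAffineNetwork(NetworkConfig.tiny(), seed=3)
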