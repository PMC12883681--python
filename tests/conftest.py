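import numpy as np
import pytest

from lesionet import synthetic
from lesionet.grid import VolumeGrid


@pytest.fixture(scope="session")
def phantom():
    return synthetic.default_phantom()


@pytest.fixture(scope="session")
def grid(phantom):
    return phantom.grid


@pytest.fixture
def tiny_grid():
    return VolumeGrid.isotropic((5, 5, 5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
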