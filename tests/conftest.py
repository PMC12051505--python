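import numpy as np
import pytest

from zsa2a import DetectorArray, Phantom, make_spherical_array


@pytest.fixture(scope="session")
def box():
    return np.array([[-12.8, -12.8, -12.8], [12.8, 12.8, 12.8]])


@pytest.fixture(scope="session")
def small_array():
    return make_spherical_array(128, 60.0)


@pytest.fixture(scope="session")
def single_sphere(box):
    # one voxel-scale absorber off-centre
    return Phantom(np.array([[3.0, -2.0, 1.0, 0.8, 1.0]]), box)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def zero_model(x):
    """g = 0: the identity-free baseline used by the worked loss examples."""
    return np.zeros_like(x)
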