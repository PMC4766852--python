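import numpy as np
import pytest

from swprop import make_network


@pytest.fixture
def triangle():
    """Binary K_3."""
    m = np.ones((3, 3)) - np.eye(3)
    return make_network(m)


@pytest.fixture
def star4():
    """Binary star: one hub, three leaves — no triangles."""
    m = np.zeros((4, 4))
    m[0, 1:] = m[1:, 0] = 1.0
    return make_network(m)


@pytest.fixture
def path3():
    """Binary path a-b-c."""
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = 1.0
    m[1, 2] = m[2, 1] = 1.0
    return make_network(m)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
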