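import numpy as np
import pytest

from lumenflow.network import TubularNetwork, build_honeycomb


@pytest.fixture(scope="session")
def honeycomb33():
    return build_honeycomb(3, 3, 1.0)


@pytest.fixture(scope="session")
def single_tubule():
    """One 1 µm tubule between two exit nodes."""
    return TubularNetwork(
        np.array([0, 1]), np.array([[0.0, 0.0], [1.0, 0.0]]),
        ["exit", "exit"], np.array([[0, 1]]), np.array([1.0]),
        np.array([0.03]))


@pytest.fixture(scope="session")
def long_tubule():
    """A 200 µm tubule for free axial diffusion checks."""
    return TubularNetwork(
        np.array([0, 1]), np.array([[0.0, 0.0], [200.0, 0.0]]),
        ["exit", "exit"], np.array([[0, 1]]), np.array([200.0]),
        np.array([0.03]))


@pytest.fixture(scope="session")
def triangle():
    return TubularNetwork(
        np.array([0, 1, 2]),
        np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]]),
        ["exit", "normal", "normal"],
        np.array([[0, 1], [1, 2], [0, 2]]),
        np.ones(3), np.full(3, 0.03))
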