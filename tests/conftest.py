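import numpy as np
import pytest

from freqlayer.bands import ALPHA, THETA
from freqlayer.netmodels import diagonal_coupling, er_layer
from freqlayer.network import InterlayerCoupling, LayerGraph, SupraNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def k2_layer():
    return LayerGraph(np.array([[0.0, 1.0], [1.0, 0.0]]), name="k2")


@pytest.fixture
def path3_layer():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 1.0
    W[1, 2] = W[2, 1] = 1.0
    return LayerGraph(W, name="path3")


@pytest.fixture
def er_pair():
    """Two connected ER layers, N=60."""
    return er_layer(60, 0.2, seed=11), er_layer(60, 0.2, seed=22)


@pytest.fixture
def small_multiplex(er_pair):
    a, b = er_pair
    return SupraNetwork([a, b], {(0, 1): diagonal_coupling(60, 0.5)})


@pytest.fixture
def two_bands():
    return (THETA, ALPHA)
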