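import numpy as np
import pytest

from connstat.io import ConnectivityMatrix
from connstat.regions import default_region_table, generic_region_table


def random_symmetric_matrix(n, rng, density=1.0, scale=10.0):
    """Random symmetric nonnegative matrix with zero diagonal."""
    W = rng.uniform(0.1, scale, size=(n, n))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        W = W * mask
    W = np.triu(W, k=1)
    return W + W.T


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def region98():
    return default_region_table()


@pytest.fixture
def make_matrix():
    """Factory: wrap a raw symmetric array into a ConnectivityMatrix."""

    def _make(W):
        return ConnectivityMatrix(np.asarray(W, dtype=float), generic_region_table(len(W)))

    return _make


@pytest.fixture
def random_matrix(rng, make_matrix):
    def _make(n, density=1.0, scale=10.0):
        return make_matrix(random_symmetric_matrix(n, rng, density, scale))

    return _make
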