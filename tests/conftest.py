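import numpy as np
import pytest
import scipy.sparse as sp

from driverplex.graph import MultiplexGraph
from driverplex.universe import GeneUniverse


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_adjacency(n, density, rng, directed=True):
    a = (rng.random((n, n)) < density).astype(float)
    np.fill_diagonal(a, 0.0)
    if not directed:
        a = np.triu(a, 1)
        a = a + a.T
    return sp.csr_matrix(a)


@pytest.fixture
def toy_multiplex(rng):
    """7-node, 3-layer multiplex (2 directed + 1 undirected), 5 features."""
    n = 7
    layers = [random_adjacency(n, 0.4, rng, directed=True),
              random_adjacency(n, 0.3, rng, directed=True),
              random_adjacency(n, 0.4, rng, directed=False)]
    X = rng.normal(size=(n, 5))
    universe = GeneUniverse([f"g{i}" for i in range(n)])
    return MultiplexGraph(universe, layers, [True, True, False], X)


@pytest.fixture
def easy_synth():
    from driverplex.simulate import generate, preset
    return generate(preset("easy", n=120, n_positives=24, seed=3))
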