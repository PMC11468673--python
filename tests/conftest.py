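import numpy as np
import pytest

import eigsearch as eg


@pytest.fixture
def k3() -> eg.Graph:
    """Unweighted triangle."""
    return eg.Graph(X=np.ones((3, 2)), edges=[(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0)])


@pytest.fixture
def path3() -> eg.Graph:
    """Path a-b-c (nodes 0-1-2)."""
    return eg.Graph(X=np.ones((3, 2)), edges=[(0, 1, 1.0), (1, 2, 1.0)])


@pytest.fixture
def probe() -> eg.FunctionPredictor:
    """p(class 1) = (#unit edges)/4; affine occlusion oracle."""
    return eg.edge_count_probe(denominator=4.0)


@pytest.fixture
def two_edge_graph() -> eg.Graph:
    """Two disjoint edges: (0,1) is edge a, (2,3) is edge b."""
    return eg.Graph(X=np.ones((4, 1)), edges=[(0, 1, 1.0), (2, 3, 1.0)])


def graph_with_edges(num_edges: int, seed: int = 0) -> eg.Graph:
    """Random connected-ish test graph with an exact edge count."""
    rng = np.random.default_rng(seed)
    for attempt in range(10_000):
        n = max(4, int(np.ceil((1 + np.sqrt(1 + 8 * num_edges)) / 2)) + 3)
        g = eg.random_graph(n, 0.5, seed=int(rng.integers(2**31 - 1)))
        if g.num_edges == num_edges:
            return g
    raise RuntimeError(f"could not sample a graph with {num_edges} edges")
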