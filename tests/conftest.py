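import numpy as np
import pytest

from netnc.benchmark import synthetic_network
from netnc.graph_core import FunctionalNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    return FunctionalNetwork.from_edges(
        [("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.7)]
    )


@pytest.fixture(scope="session")
def fixture_network():
    """Small planted-partition network shared across tests: 4 modules of 25
    genes over 600 background genes."""
    rng = np.random.default_rng(777)
    return synthetic_network(
        n_pathways=4, genes_per_pathway=25, n_background=600,
        p_within=0.35, p_between=0.01, rng=rng,
    )


def random_graph_network(n, p, rng):
    """Erdos-Renyi network helper used by oracle tests."""
    names = [f"n{i:03d}" for i in range(n)]
    net = FunctionalNetwork.from_edges([], nodes=names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(names[i], names[j], 0.9)
    return net
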