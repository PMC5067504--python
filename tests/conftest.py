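import networkx as nx
import numpy as np
import pytest

from t2di.config import SimConfig
from t2di.network import Network


@pytest.fixture
def small_config():
    """A fast-but-nontrivial synthetic study configuration."""
    return SimConfig(seed=3, n_genes=200, module_size=20, n_seeds=6)


def network_from_nx(graph: nx.Graph, prefix: str = "N") -> Network:
    net = Network()
    for n in graph.nodes:
        net.add_node(f"{prefix}{n:04d}" if isinstance(n, int) else str(n))
    for a, b in graph.edges:
        na = f"{prefix}{a:04d}" if isinstance(a, int) else str(a)
        nb = f"{prefix}{b:04d}" if isinstance(b, int) else str(b)
        net.add_edge(na, nb)
    return net


@pytest.fixture
def path_network():
    """Path a-b-c-d-e."""
    net = Network.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
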