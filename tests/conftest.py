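import networkx as nx
import numpy as np
import pytest

from ican.network_build import WeightedNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_weighted(edges):
    """WeightedNetwork from (a, b, w) triples."""
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return WeightedNetwork(graph=g)


@pytest.fixture
def path_network():
    """A-B-C-D path with varied weights."""
    return make_weighted([("A", "B", 1.0), ("B", "C", 0.5), ("C", "D", 0.25)])


def random_weighted_network(rng, n_nodes=50, p_edge=0.1):
    g = nx.gnp_random_graph(n_nodes, p_edge, seed=int(rng.integers(2**31)))
    # keep the largest component so walks are well-defined
    giant = max(nx.connected_components(g), key=len)
    g = g.subgraph(giant).copy()
    g = nx.relabel_nodes(g, {i: f"G{i:03d}" for i in g.nodes})
    for a, b in g.edges:
        g[a][b]["weight"] = float(rng.uniform(0.05, 1.0))
    return WeightedNetwork(graph=g)
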