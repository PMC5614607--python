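import networkx as nx
import numpy as np
import pytest

from htsnet.core import BioNetwork, GeneScoreTable


@pytest.fixture
def toy_net():
    """Path-and-branch toy graph: A-B, A-C, B-D, C-E."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("A", "C"), ("B", "D"), ("C", "E")])
    return BioNetwork(kind="interactome", graph=g)


@pytest.fixture
def toy_scores():
    return GeneScoreTable(
        entries={"A": 1.0, "B": 2.0, "C": -3.0, "D": 2.5, "E": 5.0}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_connected_network(n_nodes, p_edge, rng):
    """Random connected graph for property tests (spanning tree + extras)."""
    g = nx.Graph()
    nodes = [f"n{i}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    order = list(rng.permutation(n_nodes))
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        g.add_edge(nodes[order[i]], nodes[order[j]])
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(nodes[i], nodes[j])
    return BioNetwork(kind="interactome", graph=g)


def random_score_table(net, rng):
    return GeneScoreTable(
        entries={g: float(rng.normal(0, 2)) for g in sorted(net.nodes)}
    )
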