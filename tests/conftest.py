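import networkx as nx
import numpy as np
import pandas as pd
import pytest

from emdn.netio import DifferentialNetwork, OmicsMatrix, SampleLabels


def make_net(edges, layer_tag="expression", nodes=(), delta=None):
    """Build a DifferentialNetwork from (u, v, w) triples."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return DifferentialNetwork(graph=g, layer_tag=layer_tag, delta=delta)


@pytest.fixture
def triangle_pendant():
    """Triangle {a,b,c} plus pendant edge c-d, unit weights, one layer."""
    return make_net([("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 1.0),
                     ("c", "d", 1.0)])


@pytest.fixture
def clique_pair():
    """Two identical layers, each a disconnected 6-clique plus a far triangle."""
    edges = [(f"g{i}", f"g{j}", 1.0) for i in range(6) for j in range(i + 1, 6)]
    edges += [("x1", "x2", 1.0), ("x1", "x3", 1.0), ("x2", "x3", 1.0)]
    return [make_net(edges, "expression"), make_net(edges, "methylation")]


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.normal(size=(6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(8)],
    )
    return OmicsMatrix(data=data, layer_tag="expression")


@pytest.fixture
def tumor_normal_labels():
    return SampleLabels(
        labels={f"s{j}": ("tumor" if j < 4 else "normal") for j in range(8)}
    )
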