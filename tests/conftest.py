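import pytest

from orthospect.graph import (
    PSEUDO_SPECIES,
    ConnectedComponent,
    Graph,
    connected_components,
)


def build_graph(edges, n_nodes=None, species=None):
    """Graph from integer edge tuples (u, v[, w]).

    ``species`` optionally maps node index -> species label; unlabeled
    nodes get the pseudo-species.
    """
    species = species or {}
    g = Graph()
    max_node = max((max(e[0], e[1]) for e in edges), default=-1)
    n = max(n_nodes or 0, max_node + 1)
    for i in range(n):
        g.add_node(species.get(i, PSEUDO_SPECIES), f"n{i}")
    for e in edges:
        w = e[2] if len(e) == 3 else 1.0
        g.add_edge(e[0], e[1], w)
    return g


def single_component(edges, n_nodes=None, species=None) -> ConnectedComponent:
    comps = connected_components(build_graph(edges, n_nodes, species))
    assert len(comps) == 1, "test graph must be connected"
    return comps[0]


def path_edges(n):
    return [(i, i + 1) for i in range(n - 1)]


def complete_edges(n):
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def star_edges(n):
    return [(0, i) for i in range(1, n)]


@pytest.fixture
def k5():
    return single_component(complete_edges(5))


@pytest.fixture
def p3():
    return single_component(path_edges(3))
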