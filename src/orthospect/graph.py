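"""Space-efficient undirected weighted graph on an edge list.

Nodes are (species_id, protein_id) pairs mapped to dense integer indices.
Connected components are extracted by breadth-first search; components and
induced subgraphs are lightweight views onto the parent graph, holding a
node subset and the induced edge subset (edges store bitscore weights).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

log = logging.getLogger(__name__)

NodeKey = tuple[str, str]  # (species_id, protein_id)
Edge = tuple[int, int, float]  # (u, v, weight) with u < v

#: species label assigned to nodes of plain graphs with no species annotation
PSEUDO_SPECIES = "_"


class Graph:
    """Undirected weighted graph over (species, protein) nodes."""

    def __init__(self) -> None:
        self._index: dict[NodeKey, int] = {}
        self._names: list[NodeKey] = []
        self._edges: dict[tuple[int, int], float] = {}

    # -- construction -------------------------------------------------

    def add_node(self, species_id: str, protein_id: str) -> int:
        key = (species_id, protein_id)
        idx = self._index.get(key)
        if idx is None:
            idx = len(self._names)
            self._index[key] = idx
            self._names.append(key)
        return idx

    def add_edge(self, u: int, v: int, weight: float) -> None:
        """Add an undirected edge; duplicates keep the maximum weight."""
        if u == v:
            log.warning("self-loop on node %s dropped", self._names[u])
            return
        if weight <= 0:
            raise ValueError("edge weight must be positive")
        key = (u, v) if u < v else (v, u)
        prev = self._edges.get(key)
        if prev is None or weight > prev:
            self._edges[key] = weight

    # -- accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._names)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node_key(self, idx: int) -> NodeKey:
        return self._names[idx]

    def node_index(self, species_id: str, protein_id: str) -> int:
        return self._index[(species_id, protein_id)]

    def __contains__(self, key: NodeKey) -> bool:
        return key in self._index

    def edges(self) -> Iterator[Edge]:
        for (u, v), w in self._edges.items():
            yield u, v, w

    def sorted_edges(self) -> list[Edge]:
        return sorted((u, v, w) for (u, v), w in self._edges.items())


@dataclass(frozen=True)
class ConnectedComponent:
    """Node subset of a parent graph together with its induced edges.

    ``node_indices`` are sorted global indices; ``edges`` use global indices
    with u < v.  The component is expected to be connected (constructors in
    this module guarantee it).
    """

    parent: Graph
    node_indices: tuple[int, ...]
    edges: tuple[Edge, ...]

    @property
    def n(self) -> int:
        return len(self.node_indices)

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(self.parent.node_key(i)[0] for i in self.node_indices)

    def node_keys(self) -> list[NodeKey]:
        return [self.parent.node_key(i) for i in self.node_indices]

    def local_index(self) -> dict[int, int]:
        return {g: i for i, g in enumerate(self.node_indices)}

    def adjacency(self) -> list[list[int]]:
        """Unweighted adjacency lists in local indices."""
        local = self.local_index()
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for u, v, _w in self.edges:
            lu, lv = local[u], local[v]
            adj[lu].append(lv)
            adj[lv].append(lu)
        return adj

    def degrees(self) -> list[int]:
        local = self.local_index()
        deg = [0] * self.n
        for u, v, _w in self.edges:
            deg[local[u]] += 1
            deg[local[v]] += 1
        return deg


def _components_of(
    parent: Graph, nodes: Iterable[int], edges: Iterable[Edge]
) -> list[ConnectedComponent]:
    """BFS decomposition of an arbitrary (node subset, edge subset) pair."""
    nodes = sorted(set(nodes))
    node_set = set(nodes)
    adj: dict[int, list[tuple[int, float]]] = {u: [] for u in nodes}
    edge_list: list[Edge] = []
    for u, v, w in edges:
        if u in node_set and v in node_set:
            adj[u].append((v, w))
            adj[v].append((u, w))
            edge_list.append((u, v, w) if u < v else (v, u, w))

    seen: set[int] = set()
    out: list[ConnectedComponent] = []
    for start in nodes:
        if start in seen:
            continue
        comp_nodes = [start]
        seen.add(start)
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v, _w in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp_nodes.append(v)
                    queue.append(v)
        comp_set = set(comp_nodes)
        comp_edges = tuple(
            sorted(e for e in edge_list if e[0] in comp_set)
        )
        out.append(
            ConnectedComponent(parent, tuple(sorted(comp_nodes)), comp_edges)
        )
    out.sort(key=lambda c: (-c.n, c.node_indices[0]))
    return out


def connected_components(graph: Graph) -> list[ConnectedComponent]:
    """Maximal connected components, largest first (ties: smallest node index)."""
    return _components_of(graph, range(graph.n_nodes), graph.edges())


def induced_subgraph(
    component: ConnectedComponent, node_subset: Iterable[int]
) -> list[ConnectedComponent]:
    """Connected components of the subgraph induced by ``node_subset``.

    The subset need not be connected; edge weights are preserved.
    """
    subset = set(node_subset)
    if not subset <= set(component.node_indices):
        raise ValueError("node_subset is not contained in the component")
    return _components_of(component.parent, subset, component.edges)


def components_from_edges(
    component: ConnectedComponent, kept_edges: Sequence[Edge]
) -> list[ConnectedComponent]:
    """Re-decompose a component after edge removal; all nodes are retained."""
    return _components_of(component.parent, component.node_indices, kept_edges)


def species_coverage(component: ConnectedComponent) -> frozenset[str]:
    """Distinct species labels among the component's nodes."""
    return component.species_set
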