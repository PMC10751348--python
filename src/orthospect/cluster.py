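"""Recursive spectral decomposition of components into co-orthologous groups.

Two driver modes exist:

* **default mode** — a component is accepted as a group once its normalized
  algebraic connectivity lambda2 / n reaches the threshold ``alpha``;
  otherwise it is bisected along the Fiedler vector's sign pattern and the
  connected pieces are processed recursively.
* **core mode** — the connectivity threshold is ignored; a proposed split
  is accepted only while at least one side still covers every species of
  the current component, on the premise that a group of single-copy
  orthologs should span all species.  A component whose proteins-per-species
  ratio exceeds ``core_max_prots`` is split regardless, so that inflated
  mixtures of families cannot hide behind full coverage.

Components above ``maxnodes`` are first broken up by bitscore flooding.
The public surface is the :class:`SpectralOrthoClustering` estimator;
:func:`cluster_component`, :func:`core_cluster_component` and
:func:`cluster_graph` are thin functional wrappers.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .flooding import flood
from .graph import (
    ConnectedComponent,
    Graph,
    NodeKey,
    connected_components,
    induced_subgraph,
)
from .params import ClusterParams
from .spectral import (
    FiedlerResult,
    bisect,
    normalized_connectivity,
    solve_fiedler,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthoGroup:
    """A reported co-orthologous protein set.

    ``accepted_connectivity`` is the normalized connectivity (lambda2 / n)
    at which the group was accepted; singletons and pairs accepted
    trivially carry 1.
    """

    members: frozenset[NodeKey]
    accepted_connectivity: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a group must have at least one member")

    @property
    def protein_count(self) -> int:
        return len(self.members)

    @property
    def species_count(self) -> int:
        return len({species for species, _ in self.members})

    def sort_key(self) -> tuple:
        return (-self.protein_count, min(self.members))


def _group_of(comp: ConnectedComponent, connectivity: float) -> OrthoGroup:
    return OrthoGroup(
        members=frozenset(comp.node_keys()),
        accepted_connectivity=connectivity,
    )


def _solve(comp: ConnectedComponent, params: ClusterParams) -> FiedlerResult:
    return solve_fiedler(
        comp,
        dense_solver_max_n=params.dense_solver_max_n,
        tol=params.power_tol,
        max_iter=params.power_max_iter,
        seed=params.component_seed(comp.node_indices[0]),
    )


def cluster_component(
    component: ConnectedComponent, params: ClusterParams | None = None
) -> list[OrthoGroup]:
    """Default-mode recursive clustering of one connected component."""
    params = params or ClusterParams()
    out: list[OrthoGroup] = []
    stack = [component]
    while stack:
        comp = stack.pop()
        if comp.n > params.maxnodes:
            log.info("flooding component of size %d", comp.n)
            stack.extend(flood(comp, params))
            continue
        if comp.n <= 2:
            out.append(_group_of(comp, 1.0))
            continue
        fied = _solve(comp, params)
        conn = normalized_connectivity(comp, fied)
        if conn >= params.alpha:
            out.append(_group_of(comp, conn))
            continue
        side_a, side_b = bisect(comp, fied)
        stack.extend(induced_subgraph(comp, side_a))
        stack.extend(induced_subgraph(comp, side_b))
    out.sort(key=OrthoGroup.sort_key)
    return out


def core_cluster_component(
    component: ConnectedComponent, params: ClusterParams | None = None
) -> list[OrthoGroup]:
    """Core-mode clustering: split while species coverage is preserved.

    The coverage requirement is evaluated against the species set of the
    component at the current recursion level.  A component kept together by
    the coverage rule is still split when its proteins-per-species ratio
    exceeds ``core_max_prots``.
    """
    params = params or ClusterParams()
    out: list[OrthoGroup] = []
    stack = [component]
    while stack:
        comp = stack.pop()
        if comp.n > params.maxnodes:
            stack.extend(flood(comp, params))
            continue
        if comp.n == 1:
            out.append(_group_of(comp, 1.0))
            continue
        if comp.n == 2:
            fied = None
            conn = 1.0
            side_a = (comp.node_indices[0],)
            side_b = (comp.node_indices[1],)
        else:
            fied = _solve(comp, params)
            conn = normalized_connectivity(comp, fied)
            side_a, side_b = bisect(comp, fied)
        coverage = comp.species_set
        side_species = [
            {comp.parent.node_key(i)[0] for i in side}
            for side in (side_a, side_b)
        ]
        keeps_coverage = any(s == coverage for s in side_species)
        too_big = comp.n / len(coverage) > params.core_max_prots
        if keeps_coverage or too_big:
            stack.extend(induced_subgraph(comp, side_a))
            stack.extend(induced_subgraph(comp, side_b))
        else:
            out.append(_group_of(comp, conn))
    out.sort(key=OrthoGroup.sort_key)
    return out


def cluster_graph(
    graph: Graph,
    params: ClusterParams | None = None,
    workers: int = 1,
    keep_singletons: bool = True,
) -> list[OrthoGroup]:
    """Cluster every connected component of a graph.

    Components are processed independently on a worker pool; each component
    derives its solver seed from the run seed and its smallest node index,
    and the final group list is sorted canonically, so the output is
    identical for any worker count.
    """
    params = params or ClusterParams()
    comps = connected_components(graph)
    driver = core_cluster_component if params.core_mode else cluster_component
    if workers > 1 and len(comps) > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(lambda c: driver(c, params), comps))
    else:
        results = [driver(c, params) for c in comps]
    groups = [g for sub in results for g in sub]
    if not keep_singletons:
        groups = [g for g in groups if g.protein_count > 1]
    groups.sort(key=OrthoGroup.sort_key)
    log.info(
        "clustered %d components of %d nodes into %d groups",
        len(comps),
        graph.n_nodes,
        len(groups),
    )
    return groups


def groups_to_labels(graph: Graph, groups: list[OrthoGroup]) -> np.ndarray:
    """Integer label per graph node (in node-index order) from a group list."""
    labels = np.full(graph.n_nodes, -1, dtype=int)
    for gi, grp in enumerate(groups):
        for key in grp.members:
            labels[graph.node_index(*key)] = gi
    return labels


class SpectralOrthoClustering(BaseEstimator, ClusterMixin):
    """Recursive spectral clustering of a similarity graph into groups.

    Scikit-learn-style estimator: ``fit`` takes a :class:`Graph` (or a
    square symmetric adjacency / affinity matrix, dense or sparse, whose
    entries are bitscore weights) and exposes

    - ``labels_`` — group index per node, in node order;
    - ``groups_`` — the :class:`OrthoGroup` list, canonically sorted;
    - ``n_groups_`` — number of groups.

    Parameters mirror the clustering fields of :class:`ClusterParams`;
    see there for semantics and defaults.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        core_mode: bool = False,
        core_max_prots: int = 10,
        maxnodes: int = 32768,
        flood_significance: float = 0.05,
        dense_solver_max_n: int = 4096,
        power_tol: float = 1e-7,
        power_max_iter: int = 100_000,
        workers: int = 1,
        random_state: int = 0,
    ) -> None:
        self.alpha = alpha
        self.core_mode = core_mode
        self.core_max_prots = core_max_prots
        self.maxnodes = maxnodes
        self.flood_significance = flood_significance
        self.dense_solver_max_n = dense_solver_max_n
        self.power_tol = power_tol
        self.power_max_iter = power_max_iter
        self.workers = workers
        self.random_state = random_state

    def _params(self) -> ClusterParams:
        return ClusterParams(
            alpha=self.alpha,
            core_mode=self.core_mode,
            core_max_prots=self.core_max_prots,
            maxnodes=self.maxnodes,
            flood_significance=self.flood_significance,
            dense_solver_max_n=self.dense_solver_max_n,
            power_tol=self.power_tol,
            power_max_iter=self.power_max_iter,
            seed=self.random_state,
        )

    @staticmethod
    def _as_graph(X) -> Graph:
        if isinstance(X, Graph):
            return X
        import scipy.sparse

        if scipy.sparse.issparse(X):
            X = X.toarray()
        arr = np.asarray(X)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("adjacency input must be a square matrix")
        if not np.allclose(arr, arr.T):
            raise ValueError("adjacency input must be symmetric")
        graph = Graph()
        from .graph import PSEUDO_SPECIES

        n = arr.shape[0]
        for i in range(n):
            graph.add_node(PSEUDO_SPECIES, str(i))
        for i in range(n):
            for j in range(i + 1, n):
                if arr[i, j] != 0:
                    graph.add_edge(i, j, float(arr[i, j]))
        return graph

    def fit(self, X, y=None) -> "SpectralOrthoClustering":
        graph = self._as_graph(X)
        self.graph_ = graph
        self.groups_ = cluster_graph(
            graph, self._params(), workers=self.workers
        )
        self.labels_ = groups_to_labels(graph, self.groups_)
        self.n_groups_ = len(self.groups_)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
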