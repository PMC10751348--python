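"""Adaptive (pseudo-)reciprocal best-hit graph construction.

Directed similarity hits are turned into an undirected orthology-candidate
graph.  For every query and target species, the best hit *and* every
alternative hit whose bitscore reaches ``f * best`` are kept (the adaptive
extension that admits co-orthologs); an undirected edge a-b exists iff b is
in a's kept set and a is in b's kept set.

Two modes are supported:

* ``classic`` — both search directions per species pair were computed and
  are supplied;
* ``pseudo`` — exactly one direction per species pair is supplied and the
  reverse direction is synthesized: bitscore, identity and alignment length
  are direction-symmetric and are copied, while the missing E-value is
  estimated from the new query's length ``l``, the database size ``|S_n|``
  of the original query species, and the bitscore ``b`` as

      e = l * |S_n| / 2**b .
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator

from .graph import Graph, NodeKey
from .io import ProteinRegistry, SimilarityHit
from .params import ClusterParams

_LOG2_TINY = -1075.0  # below the smallest subnormal double


@dataclass(frozen=True)
class RbhEdge:
    """One undirected reciprocal-best-hit edge with both directional scores.

    ``protein_a`` precedes ``protein_b`` under the natural (species, protein)
    order, giving every edge a unique canonical orientation.
    """

    protein_a: NodeKey
    protein_b: NodeKey
    bitscore_ab: float
    bitscore_ba: float
    evalue_ab: float
    evalue_ba: float

    def __post_init__(self) -> None:
        if self.protein_a >= self.protein_b:
            raise ValueError("edge must be canonically oriented (a < b)")
        if self.protein_a[0] == self.protein_b[0]:
            raise ValueError("within-species edges are not allowed")

    @property
    def weight(self) -> float:
        """Bitscore weight used in graph exports: min of the two directions."""
        return min(self.bitscore_ab, self.bitscore_ba)


class RbhGraph(Graph):
    """Graph whose edges additionally carry the reciprocal hit scores."""

    def __init__(self) -> None:
        super().__init__()
        self.edge_data: dict[tuple[int, int], RbhEdge] = {}

    def add_rbh_edge(self, edge: RbhEdge) -> None:
        u = self.add_node(*edge.protein_a)
        v = self.add_node(*edge.protein_b)
        key = (u, v) if u < v else (v, u)
        self.add_edge(u, v, edge.weight)
        self.edge_data[key] = edge


def estimate_reverse_evalue(query_length: int, db_size: int, bitscore: float) -> float:
    """E-value of the uncomputed reverse search: ``l * N / 2**b``.

    Evaluated in log space so that very large bitscores underflow cleanly to
    zero instead of raising; the result is monotone decreasing in ``b``.
    """
    if query_length < 1 or db_size < 1:
        raise ValueError("query_length and db_size must be >= 1")
    if bitscore < 0:
        raise ValueError("bitscore must be non-negative")
    # split the exponent so huge bitscores underflow gradually to zero
    # instead of overflowing an intermediate 2**b
    b_int = math.floor(bitscore)
    if b_int - math.log2(query_length) - math.log2(db_size) > -_LOG2_TINY:
        return 0.0
    frac = bitscore - b_int
    return math.ldexp(query_length * db_size * 2.0**-frac, -int(b_int))


def collapse_hsps(hits: Iterable[SimilarityHit]) -> list[SimilarityHit]:
    """Keep one hit per ordered protein pair: the highest bitscore
    (ties broken by lower E-value)."""
    best: dict[tuple[NodeKey, NodeKey], SimilarityHit] = {}
    for h in hits:
        key = (h.query_key, h.subject_key)
        cur = best.get(key)
        if cur is None or (h.bitscore, -h.evalue) > (cur.bitscore, -cur.evalue):
            best[key] = h
    return list(best.values())


def filter_hits(
    hits: Iterable[SimilarityHit],
    registry: ProteinRegistry,
    params: ClusterParams,
) -> list[SimilarityHit]:
    """Apply the E-value, identity and coverage thresholds.

    Coverage is 100 * aln_length / min(query length, subject length), which
    is symmetric under direction swap.  Self-hits and within-species hits
    are dropped here.
    """
    kept: list[SimilarityHit] = []
    for h in hits:
        if h.query_species == h.subject_species:
            continue
        if h.evalue > params.evalue_max:
            continue
        if h.identity_pct < params.min_identity_pct:
            continue
        shorter = min(
            registry.length(h.query_species, h.query_id),
            registry.length(h.subject_species, h.subject_id),
        )
        if 100.0 * h.aln_length / shorter < params.min_coverage_pct:
            continue
        kept.append(h)
    return kept


def adaptive_best(
    hits: Sequence[SimilarityHit], adaptive_factor: float
) -> list[SimilarityHit]:
    """Best hit of one query against one species plus near-best alternatives.

    With best bitscore B, every hit scoring at least ``f * B`` is kept
    (ties at the boundary included); at most one hit per subject protein
    survives (the highest-scoring one).
    """
    hits = collapse_hsps(hits)
    if not hits:
        return []
    queries = {h.query_key for h in hits}
    species = {h.subject_species for h in hits}
    if len(queries) > 1 or len(species) > 1:
        raise ValueError("adaptive_best expects one query vs one species")
    best = max(h.bitscore for h in hits)
    return [h for h in hits if h.bitscore >= adaptive_factor * best]


def synthesize_reverse_hits(
    hits: Iterable[SimilarityHit], registry: ProteinRegistry
) -> list[SimilarityHit]:
    """Mirror a forward hit table into the uncomputed reverse direction.

    Bitscore, identity and alignment length are copied; query/subject roles
    and coordinates swap; the E-value is re-estimated from the mirrored
    query's length and the forward query species' database size.
    """
    out: list[SimilarityHit] = []
    for h in hits:
        if h.subject_key not in registry:
            raise KeyError(
                f"subject protein {h.subject_id!r} ({h.subject_species}) "
                "missing from the registry"
            )
        evalue = estimate_reverse_evalue(
            registry.length(h.subject_species, h.subject_id),
            registry.db_size(h.query_species),
            h.bitscore,
        )
        out.append(
            replace(
                h,
                query_id=h.subject_id,
                subject_id=h.query_id,
                query_species=h.subject_species,
                subject_species=h.query_species,
                qstart=h.sstart,
                qend=h.send,
                sstart=h.qstart,
                send=h.qend,
                evalue=evalue,
            )
        )
    return out


def _group_by_pair(
    hits: Iterable[SimilarityHit],
) -> dict[tuple[str, str], list[SimilarityHit]]:
    tables: dict[tuple[str, str], list[SimilarityHit]] = {}
    for h in hits:
        tables.setdefault((h.query_species, h.subject_species), []).append(h)
    return tables


def _kept_sets(
    hits: Sequence[SimilarityHit],
    registry: ProteinRegistry,
    params: ClusterParams,
) -> dict[NodeKey, dict[NodeKey, SimilarityHit]]:
    """Filter one directed table, then apply the adaptive-best rule per query."""
    filtered = filter_hits(collapse_hsps(hits), registry, params)
    per_query: dict[NodeKey, list[SimilarityHit]] = {}
    for h in filtered:
        per_query.setdefault(h.query_key, []).append(h)
    kept: dict[NodeKey, dict[NodeKey, SimilarityHit]] = {}
    for query, qhits in per_query.items():
        best = max(h.bitscore for h in qhits)
        kept[query] = {
            h.subject_key: h
            for h in qhits
            if h.bitscore >= params.adaptive_factor * best
        }
    return kept


def build_rbh_graph(
    hits: Iterable[SimilarityHit],
    registry: ProteinRegistry,
    params: ClusterParams | None = None,
    mode: str = "pseudo",
) -> RbhGraph:
    """Build the undirected adaptive reciprocal-best-hit graph.

    ``hits`` is the union of all directed hit tables (each hit carries its
    species pair).  In classic mode both directions per species pair must be
    present; in pseudo mode exactly one direction per unordered pair is
    expected and the reverse is synthesized before filtering.
    """
    if mode not in ("classic", "pseudo"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or ClusterParams()
    tables = _group_by_pair(hits)

    cross = {pair for pair in tables if pair[0] != pair[1]}
    unordered = {tuple(sorted(pair)) for pair in cross}
    for a, b in sorted(unordered):
        both = ((a, b) in cross) + ((b, a) in cross)
        if mode == "classic" and both != 2:
            raise ValueError(
                f"classic mode requires both search directions for species "
                f"pair ({a}, {b}); one is missing"
            )
        if mode == "pseudo" and both != 1:
            raise ValueError(
                f"pseudo mode expects exactly one search direction for "
                f"species pair ({a}, {b}); found both"
            )
    if mode == "pseudo":
        for qs, ss in sorted(cross):
            tables[(ss, qs)] = synthesize_reverse_hits(tables[(qs, ss)], registry)

    kept = {
        pair: _kept_sets(table, registry, params)
        for pair, table in sorted(tables.items())
        if pair[0] != pair[1]
    }

    graph = RbhGraph()
    for species, protein in registry.protein_keys():
        graph.add_node(species, protein)
    for a, b in sorted(unordered):
        fwd = kept.get((a, b), {})
        rev = kept.get((b, a), {})
        for query in sorted(fwd):
            for subject in sorted(fwd[query]):
                hit_ab = fwd[query][subject]
                hit_ba = rev.get(subject, {}).get(query)
                if hit_ba is None:
                    continue
                pa, pb = sorted((query, subject))
                if pa != query:
                    hit_ab, hit_ba = hit_ba, hit_ab
                graph.add_rbh_edge(
                    RbhEdge(
                        protein_a=pa,
                        protein_b=pb,
                        bitscore_ab=hit_ab.bitscore,
                        bitscore_ba=hit_ba.bitscore,
                        evalue_ab=hit_ab.evalue,
                        evalue_ba=hit_ba.evalue,
                    )
                )
    return graph


class RbhGraphBuilder(BaseEstimator):
    """Estimator-style wrapper around :func:`build_rbh_graph`.

    Parameters mirror the hit-level thresholds of :class:`ClusterParams`;
    ``fit`` consumes the directed hits and a protein registry and exposes
    the resulting graph as ``graph_``.
    """

    def __init__(
        self,
        evalue_max: float = 1e-5,
        adaptive_factor: float = 0.95,
        min_identity_pct: float = 25.0,
        min_coverage_pct: float = 50.0,
        mode: str = "pseudo",
    ) -> None:
        self.evalue_max = evalue_max
        self.adaptive_factor = adaptive_factor
        self.min_identity_pct = min_identity_pct
        self.min_coverage_pct = min_coverage_pct
        self.mode = mode

    def fit(
        self,
        X: Iterable[SimilarityHit],
        y: None = None,
        *,
        registry: ProteinRegistry,
    ) -> "RbhGraphBuilder":
        params = ClusterParams(
            evalue_max=self.evalue_max,
            adaptive_factor=self.adaptive_factor,
            min_identity_pct=self.min_identity_pct,
            min_coverage_pct=self.min_coverage_pct,
        )
        self.graph_ = build_rbh_graph(X, registry, params, mode=self.mode)
        self.n_edges_ = self.graph_.n_edges
        return self

    def fit_transform(
        self,
        X: Iterable[SimilarityHit],
        y: None = None,
        *,
        registry: ProteinRegistry,
    ) -> RbhGraph:
        return self.fit(X, registry=registry).graph_
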