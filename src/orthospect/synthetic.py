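"""Synthetic inputs with known structure for every pipeline stage.

Two generators are provided:

* :func:`simulate_component` — random connected weighted components built
  the way the clustering evaluation set is defined: an unweighted path
  graph over ``n`` nodes guarantees connectivity, random edges between
  currently unconnected node pairs are added one by one until the requested
  density is reached, every edge gets a bitscore drawn uniformly from
  [1, 2000] and an E-value of 1/bitscore.
* :func:`simulate_hit_tables` — multi-species directed similarity hit
  tables with a planted family structure (the recovery target for
  end-to-end tests), plus the matching protein registry.  Within-family
  cross-species pairs receive high bitscores consistent in both directions
  up to an optional relative jitter; sparse background hits receive low
  bitscores.  E-values in both directions follow the analytic estimate
  e = l * |S| / 2**bitscore, so that jitter-free tables behave identically
  under the classic and the pseudo-reciprocal strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import PSEUDO_SPECIES, ConnectedComponent, Graph, NodeKey, connected_components
from .io import ProteinRecord, ProteinRegistry, ProteinSet, SimilarityHit
from .rbh import estimate_reverse_evalue


@dataclass(frozen=True)
class SimSpec:
    """Specification of one simulated weighted component."""

    n: int
    density: float
    bitscore_range: tuple[float, float] = (1.0, 2000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        if self.target_edges < self.n - 1:
            raise ValueError(
                "density too low: requested edge count falls below the "
                "connecting path's n - 1 edges"
            )

    @property
    def target_edges(self) -> int:
        return math.ceil(self.density * self.n * (self.n - 1) / 2)


def simulate_component(spec: SimSpec) -> ConnectedComponent:
    """Generate one connected weighted component per ``spec``.

    Deterministic under ``spec.seed``.  Edge weights are bitscores; the
    matching E-values are 1/bitscore by construction and need not be stored.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    graph = Graph()
    for i in range(n):
        graph.add_node(PSEUDO_SPECIES, f"n{i}")
    present: set[tuple[int, int]] = set()
    for i in range(n - 1):
        present.add((i, i + 1))
    target = spec.target_edges
    max_pairs = n * (n - 1) // 2
    # rejection-sample random unconnected pairs; near saturation fall back
    # to a shuffled enumeration of the absent pairs (same uniform law)
    while len(present) < target:
        if len(present) > 0.8 * max_pairs:
            absent = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if (i, j) not in present
            ]
            order = rng.permutation(len(absent))
            for idx in order[: target - len(present)]:
                present.add(absent[idx])
            break
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        pair = (int(min(i, j)), int(max(i, j)))
        if pair not in present:
            present.add(pair)
    lo, hi = spec.bitscore_range
    for u, v in sorted(present):
        graph.add_edge(u, v, float(rng.uniform(lo, hi)))
    comps = connected_components(graph)
    assert len(comps) == 1
    return comps[0]


@dataclass(frozen=True)
class TruthTable:
    """Ground-truth family membership of every generated protein."""

    partition: dict[NodeKey, int]

    def as_sets(self) -> list[set[NodeKey]]:
        families: dict[int, set[NodeKey]] = {}
        for key, fam in self.partition.items():
            families.setdefault(fam, set()).add(key)
        return [families[f] for f in sorted(families)]


@dataclass
class HitFixture:
    """Everything :func:`simulate_hit_tables` produces."""

    hits: list[SimilarityHit]
    truth: TruthTable
    registry: ProteinRegistry
    protein_sets: list[ProteinSet] = field(default_factory=list)

    def forward_hits(self) -> list[SimilarityHit]:
        """Only the direction with query species < subject species
        (the single computed direction for pseudo-reciprocal runs)."""
        return [
            h for h in self.hits if h.query_species < h.subject_species
        ]


def simulate_hit_tables(
    n_species: int = 3,
    n_families: int = 10,
    mean_family_size: float = 1.0,
    within_family_bitscore: tuple[float, float] = (300.0, 600.0),
    background_bitscore: tuple[float, float] = (10.0, 50.0),
    background_rate: float = 0.02,
    jitter: float = 0.0,
    seed: int = 0,
) -> HitFixture:
    """Plant a family structure and emit the directed hit tables around it.

    Each family has ``1 + Poisson(mean_family_size - 1)`` members in every
    species (so every family covers all species and ``mean_family_size=1``
    gives exactly one member per species).  Protein lengths are uniform on
    [100, 1000].  Both search directions are emitted, so classic and
    pseudo-reciprocal runs can be compared on the same fixture; ``jitter``
    perturbs the reverse bitscore relatively by up to that fraction.
    """
    if mean_family_size < 1.0:
        raise ValueError("mean_family_size must be >= 1")
    if not within_family_bitscore[0] > background_bitscore[1]:
        raise ValueError("within-family bitscores must dominate background")
    rng = np.random.default_rng(seed)
    species = [f"S{i + 1}" for i in range(n_species)]

    records: dict[str, list[ProteinRecord]] = {s: [] for s in species}
    partition: dict[NodeKey, int] = {}
    members: dict[int, dict[str, list[str]]] = {}
    for fam in range(n_families):
        members[fam] = {}
        for sp in species:
            count = 1 + int(rng.poisson(mean_family_size - 1.0))
            ids = [f"f{fam}m{k}" for k in range(count)]
            members[fam][sp] = ids
            for pid in ids:
                length = int(rng.integers(100, 1001))
                records[sp].append(ProteinRecord(pid, sp, length))
                partition[(sp, pid)] = fam
    protein_sets = [ProteinSet(sp, tuple(records[sp])) for sp in species]
    registry = ProteinRegistry(protein_sets)

    def evalue(query: NodeKey, subject: NodeKey, bitscore: float) -> float:
        return estimate_reverse_evalue(
            registry.length(*query), registry.db_size(subject[0]), bitscore
        )

    def hit(q: NodeKey, s: NodeKey, bitscore: float, identity: float,
            frac: float) -> SimilarityHit:
        aln = max(1, int(frac * min(registry.length(*q), registry.length(*s))))
        return SimilarityHit(
            query_id=q[1], subject_id=s[1],
            query_species=q[0], subject_species=s[0],
            identity_pct=identity, aln_length=aln,
            evalue=evalue(q, s, bitscore), bitscore=bitscore,
            qstart=1, qend=aln, sstart=1, send=aln,
        )

    hits: list[SimilarityHit] = []
    lo, hi = within_family_bitscore
    for fam in range(n_families):
        for i, sp_a in enumerate(species):
            for sp_b in species[i + 1:]:
                for pa in members[fam][sp_a]:
                    for pb in members[fam][sp_b]:
                        a: NodeKey = (sp_a, pa)
                        b: NodeKey = (sp_b, pb)
                        base = float(rng.uniform(lo, hi))
                        back = base
                        if jitter > 0:
                            back *= 1.0 + jitter * float(rng.uniform(-1, 1))
                        ident = float(rng.uniform(60, 100))
                        hits.append(hit(a, b, base, ident, 0.9))
                        hits.append(hit(b, a, back, ident, 0.9))

    all_keys = registry.protein_keys()
    cross_pairs = [
        (a, b) for a in all_keys for b in all_keys if a[0] < b[0]
    ]
    n_background = int(background_rate * len(cross_pairs))
    if n_background:
        blo, bhi = background_bitscore
        idx = rng.choice(len(cross_pairs), size=n_background, replace=False)
        for k in idx:
            a, b = cross_pairs[int(k)]
            score = float(rng.uniform(blo, bhi))
            ident = float(rng.uniform(25, 40))
            direction = rng.integers(0, 2)
            q, s = (a, b) if direction == 0 else (b, a)
            hits.append(hit(q, s, score, ident, 0.6))
    return HitFixture(hits, TruthTable(partition), registry, protein_sets)
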