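import math
from fractions import Fraction

import numpy as np
import pytest

from orthospect.io import ProteinRecord, ProteinRegistry, ProteinSet, SimilarityHit
from orthospect.params import ClusterParams
from orthospect.rbh import (
    adaptive_best,
    build_rbh_graph,
    estimate_reverse_evalue,
    filter_hits,
    synthesize_reverse_hits,
)
from orthospect.synthetic import simulate_hit_tables


def make_registry(lengths):
    """lengths: {species: {protein: length}}"""
    sets = [
        ProteinSet(sp, tuple(ProteinRecord(p, sp, l) for p, l in prots.items()))
        for sp, prots in lengths.items()
    ]
    return ProteinRegistry(sets)


def make_hit(q, s, bitscore, evalue=1e-30, identity=90.0, aln=100):
    return SimilarityHit(
        query_id=q[1], subject_id=s[1], query_species=q[0],
        subject_species=s[0], identity_pct=identity, aln_length=aln,
        evalue=evalue, bitscore=bitscore, qstart=1, qend=aln,
        sstart=1, send=aln,
    )


class TestFilterHits:
    REG = None

    @classmethod
    def setup_class(cls):
        cls.REG = make_registry(
            {"X": {"a": 200, "b": 200}, "Y": {"c": 200, "d": 100}}
        )

    def test_evalue_threshold(self):
        params = ClusterParams(evalue_max=1e-5)
        hit = make_hit(("X", "a"), ("Y", "c"), 100, evalue=1e-4)
        assert filter_hits([hit], self.REG, params) == []
        hit_ok = make_hit(("X", "a"), ("Y", "c"), 100, evalue=1e-6)
        assert filter_hits([hit_ok], self.REG, params) == [hit_ok]

    def test_within_species_and_self_hits_dropped(self):
        params = ClusterParams()
        hits = [
            make_hit(("X", "a"), ("X", "a"), 100),
            make_hit(("X", "a"), ("X", "b"), 100),
        ]
        assert filter_hits(hits, self.REG, params) == []

    def test_coverage_uses_shorter_protein(self):
        params = ClusterParams(min_coverage_pct=50)
        # aln 60 vs min(200, 100) = 100 -> 60% passes
        hit = make_hit(("X", "a"), ("Y", "d"), 100, aln=60)
        assert filter_hits([hit], self.REG, params) == [hit]
        # aln 60 vs min(200, 200) = 200 -> 30% fails
        hit2 = make_hit(("X", "a"), ("Y", "c"), 100, aln=60)
        assert filter_hits([hit2], self.REG, params) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_predicate(self, seed):
        rng = np.random.default_rng(seed)
        params = ClusterParams()
        hits = []
        for _ in range(10):
            q = ("X", rng.choice(["a", "b"]))
            s = (rng.choice(["X", "Y"]), rng.choice(["a", "b", "c", "d"]))
            if (s[0], s[1]) not in [("X", "a"), ("X", "b"),
                                    ("Y", "c"), ("Y", "d")]:
                continue
            hits.append(make_hit(
                q, s, float(rng.uniform(50, 500)),
                evalue=float(10.0 ** rng.uniform(-30, 0)),
                identity=float(rng.uniform(0, 100)),
                aln=int(rng.integers(10, 200)),
            ))

        def predicate(h):
            shorter = min(self.REG.length(*h.query_key),
                          self.REG.length(*h.subject_key))
            return (
                h.query_species != h.subject_species
                and h.evalue <= params.evalue_max
                and h.identity_pct >= params.min_identity_pct
                and 100.0 * h.aln_length / shorter >= params.min_coverage_pct
            )

        assert filter_hits(hits, self.REG, params) == [
            h for h in hits if predicate(h)
        ]


class TestAdaptiveBest:
    def test_threshold_at_f_times_best(self):
        hits = [
            make_hit(("X", "a"), ("Y", f"s{i}"), b)
            for i, b in enumerate([100.0, 96.0, 94.0])
        ]
        kept = adaptive_best(hits, 0.95)
        assert sorted(h.bitscore for h in kept) == [96.0, 100.0]

    def test_single_hit_kept(self):
        hits = [make_hit(("X", "a"), ("Y", "s"), 42.0)]
        assert adaptive_best(hits, 0.95) == hits

    def test_all_equal_all_kept(self):
        hits = [make_hit(("X", "a"), ("Y", f"s{i}"), 77.0) for i in range(4)]
        assert len(adaptive_best(hits, 1.0)) == 4

    def test_boundary_tie_is_kept(self):
        hits = [
            make_hit(("X", "a"), ("Y", "s0"), 100.0),
            make_hit(("X", "a"), ("Y", "s1"), 95.0),
        ]
        assert len(adaptive_best(hits, 0.95)) == 2

    def test_empty_input(self):
        assert adaptive_best([], 0.95) == []

    def test_duplicate_subject_keeps_best_hsp(self):
        hits = [
            make_hit(("X", "a"), ("Y", "s"), 100.0),
            make_hit(("X", "a"), ("Y", "s"), 99.0),
        ]
        kept = adaptive_best(hits, 0.9)
        assert [h.bitscore for h in kept] == [100.0]


class TestEstimateReverseEvalue:
    def test_bitscore_zero(self):
        assert estimate_reverse_evalue(100, 1, 0.0) == 100.0

    def test_exact_rational_example(self):
        assert estimate_reverse_evalue(50, 10, 10.0) == pytest.approx(
            float(Fraction(500, 1024)), rel=1e-14
        )

    def test_huge_bitscore_underflows_to_zero(self):
        e = estimate_reverse_evalue(100, 1000, 2000.0)
        assert e < 1e-300

    def test_monotone_decreasing_in_bitscore(self):
        values = [estimate_reverse_evalue(300, 40, b)
                  for b in [0, 1, 10, 100, 500, 1200]]
        assert values == sorted(values, reverse=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_rational_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            l = int(rng.integers(1, 5000))
            n = int(rng.integers(1, 100000))
            b = int(rng.integers(0, 900))
            exact = Fraction(l * n, 2**b)
            assert estimate_reverse_evalue(l, n, float(b)) == pytest.approx(
                float(exact), rel=1e-12
            )


class TestSynthesizeReverseHits:
    REG = None

    @classmethod
    def setup_class(cls):
        cls.REG = make_registry(
            {"X": {"a": 150}, "Y": {"b": 100}}
        )

    def test_mirror_formula(self):
        fwd = make_hit(("X", "a"), ("Y", "b"), 200.0, aln=90)
        (rev,) = synthesize_reverse_hits([fwd], self.REG)
        assert rev.query_key == ("Y", "b")
        assert rev.subject_key == ("X", "a")
        assert rev.bitscore == 200.0
        assert rev.identity_pct == fwd.identity_pct
        assert rev.aln_length == fwd.aln_length
        # |S_X| = 1 (one protein in X), l_b = 100
        assert rev.evalue == pytest.approx(100 * 1 * 2.0**-200, rel=1e-12)
        assert (rev.qstart, rev.qend) == (fwd.sstart, fwd.send)

    def test_empty_input(self):
        assert synthesize_reverse_hits([], self.REG) == []

    def test_double_mirror_preserves_bitscore(self):
        fwd = make_hit(("X", "a"), ("Y", "b"), 321.5)
        back = synthesize_reverse_hits(
            synthesize_reverse_hits([fwd], self.REG), self.REG
        )[0]
        assert back.bitscore == fwd.bitscore
        assert back.query_key == fwd.query_key

    def test_unknown_subject_rejected(self):
        fwd = make_hit(("X", "a"), ("Y", "ghost"), 100.0)
        with pytest.raises(KeyError, match="ghost"):
            synthesize_reverse_hits([fwd], self.REG)


# ---------------------------------------------------------------------------
# full graph construction


def random_classic_fixture(rng, n_species=3, n_prot=5):
    lengths = {
        f"S{i}": {f"p{i}{j}": int(rng.integers(100, 400))
                  for j in range(n_prot)}
        for i in range(n_species)
    }
    registry = make_registry(lengths)
    keys = registry.protein_keys()
    hits = []
    for q in keys:
        for s in keys:
            if q[0] == s[0] or rng.random() > 0.5:
                continue
            hits.append(make_hit(
                q, s, float(rng.uniform(50, 500)),
                evalue=float(10.0 ** rng.uniform(-40, -2)),
                identity=float(rng.uniform(20, 100)),
                aln=int(rng.integers(40, 300)),
            ))
    # make every direction "computed" even when it has no surviving rows:
    # guarantee at least one hit per ordered species pair
    species = sorted(lengths)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            for qs, ss in [(a, b), (b, a)]:
                if not any(h.query_species == qs and h.subject_species == ss
                           for h in hits):
                    hits.append(make_hit(
                        (qs, f"p{qs[1]}0"), (ss, f"p{ss[1]}0"), 10.0,
                        evalue=1.0, identity=10.0, aln=10,
                    ))
    return registry, hits


def oracle_edges(hits, registry, params):
    """Brute-force reciprocal-criterion evaluation over all protein pairs."""
    best = {}
    for h in hits:
        key = (h.query_key, h.subject_key)
        cur = best.get(key)
        if cur is None or (h.bitscore, -h.evalue) > (cur.bitscore, -cur.evalue):
            best[key] = h

    def passes(h):
        shorter = min(registry.length(*h.query_key),
                      registry.length(*h.subject_key))
        return (
            h.query_species != h.subject_species
            and h.evalue <= params.evalue_max
            and h.identity_pct >= params.min_identity_pct
            and 100.0 * h.aln_length / shorter >= params.min_coverage_pct
        )

    surviving = {k: h for k, h in best.items() if passes(h)}

    def in_kept_set(q, s):
        h = surviving.get((q, s))
        if h is None:
            return False
        peers = [
            h2.bitscore for (q2, s2), h2 in surviving.items()
            if q2 == q and s2[0] == s[0]
        ]
        return h.bitscore >= params.adaptive_factor * max(peers)

    edges = set()
    for a in registry.protein_keys():
        for b in registry.protein_keys():
            if a < b and a[0] != b[0]:
                if in_kept_set(a, b) and in_kept_set(b, a):
                    edges.add((a, b))
    return edges


def graph_edge_keys(graph):
    return {
        tuple(sorted((graph.node_key(u), graph.node_key(v))))
        for u, v, _w in graph.edges()
    }


class TestBuildRbhGraph:
    def test_mutual_best_gives_edge(self):
        registry = make_registry({"X": {"a": 100}, "Y": {"b": 100}})
        hits = [
            make_hit(("X", "a"), ("Y", "b"), 200.0),
            make_hit(("Y", "b"), ("X", "a"), 198.0),
        ]
        g = build_rbh_graph(hits, registry, mode="classic")
        assert graph_edge_keys(g) == {(("X", "a"), ("Y", "b"))}
        edge = next(iter(g.edge_data.values()))
        assert edge.bitscore_ab == 200.0 and edge.bitscore_ba == 198.0

    def test_non_reciprocal_gives_no_edge(self):
        registry = make_registry({"X": {"a": 100}, "Y": {"b": 100, "c": 100}})
        hits = [
            make_hit(("X", "a"), ("Y", "b"), 200.0),
            # b's best toward X is a, but a falls below f*B: no edge
            make_hit(("Y", "b"), ("X", "a"), 100.0),
            make_hit(("Y", "c"), ("X", "a"), 150.0),
        ]
        g = build_rbh_graph(hits, registry, mode="classic",
                            params=ClusterParams(adaptive_factor=0.95))
        # a<->b reciprocal (a's only option; b's best toward X is a)
        assert (("X", "a"), ("Y", "b")) in graph_edge_keys(g)
        hits2 = [
            make_hit(("X", "a"), ("Y", "b"), 200.0),
            make_hit(("X", "a"), ("Y", "c"), 100.0),  # below 0.95 * 200
            make_hit(("Y", "c"), ("X", "a"), 150.0),
        ]
        g2 = build_rbh_graph(hits2 + [make_hit(("Y", "b"), ("X", "a"), 10.0,
                                               evalue=1.0, identity=5.0)],
                             registry, mode="classic")
        assert (("X", "a"), ("Y", "c")) not in graph_edge_keys(g2)

    def test_missing_direction_rejected_in_classic_mode(self):
        registry = make_registry({"X": {"a": 100}, "Y": {"b": 100}})
        hits = [make_hit(("X", "a"), ("Y", "b"), 200.0)]
        with pytest.raises(ValueError, match="classic"):
            build_rbh_graph(hits, registry, mode="classic")

    def test_both_directions_rejected_in_pseudo_mode(self):
        registry = make_registry({"X": {"a": 100}, "Y": {"b": 100}})
        hits = [
            make_hit(("X", "a"), ("Y", "b"), 200.0),
            make_hit(("Y", "b"), ("X", "a"), 200.0),
        ]
        with pytest.raises(ValueError, match="pseudo"):
            build_rbh_graph(hits, registry, mode="pseudo")

    @pytest.mark.parametrize("seed", range(10))
    def test_classic_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        registry, hits = random_classic_fixture(rng)
        params = ClusterParams()
        g = build_rbh_graph(hits, registry, params, mode="classic")
        assert graph_edge_keys(g) == oracle_edges(hits, registry, params)

    def test_no_within_species_edges_or_self_loops(self):
        fx = simulate_hit_tables(n_species=3, n_families=5, seed=11)
        g = build_rbh_graph(fx.hits, fx.registry, mode="classic")
        for u, v, _w in g.edges():
            assert u != v
            assert g.node_key(u)[0] != g.node_key(v)[0]

    def test_hit_order_invariance(self):
        fx = simulate_hit_tables(n_species=3, n_families=5, seed=4)
        g1 = build_rbh_graph(fx.hits, fx.registry, mode="classic")
        g2 = build_rbh_graph(fx.hits[::-1], fx.registry, mode="classic")
        assert graph_edge_keys(g1) == graph_edge_keys(g2)

    @pytest.mark.parametrize("seed", range(5))
    def test_pseudo_equals_classic_on_jitter_free_fixture(self, seed):
        fx = simulate_hit_tables(n_species=4, n_families=6,
                                 mean_family_size=1.5, jitter=0.0, seed=seed)
        classic = build_rbh_graph(fx.hits, fx.registry, mode="classic")
        pseudo = build_rbh_graph(fx.forward_hits(), fx.registry, mode="pseudo")
        assert graph_edge_keys(classic) == graph_edge_keys(pseudo)
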