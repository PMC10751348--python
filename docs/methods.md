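# Methods

## Problem and model

Orthology inference at scale is graph-shaped. Pairwise protein similarity
searches between species yield directed, scored hits; reciprocity of
(near-)best hits is evidence of orthology; and the resulting undirected
graph decomposes into connected components that mix true co-orthologous
groups with bridge- and hub-induced conglomerates. `orthospect` implements
the two halves of this model — building the reciprocal graph and cutting the
components back into coherent groups — together with the metrics and
synthetic generators needed to validate both.

### Adaptive reciprocal best hits

For every query protein a and target species T, let B be the highest
bitscore among a's surviving hits into T. The kept set of a against T is
every hit with bitscore ≥ f·B (default f = 0.95, ties at the boundary
included; with several HSPs per protein pair only the highest-bitscore one
is considered at all). An undirected edge a–b is drawn iff b lies in a's
kept set and a in b's kept set. f = 1 degenerates to the classic strict
reciprocal best hit; f < 1 admits co-orthologs whose scores closely
approach the best match.

Hits first pass three filters: E-value ≤ `evalue_max` (default 1e−5),
percent identity ≥ `min_identity_pct` (default 25), and coverage ≥
`min_coverage_pct` (default 50) where coverage = 100·aln_length /
min(query length, subject length). The minimum-length denominator makes
coverage symmetric under direction swap, which pseudo-reciprocal mode
requires. Self-hits and within-species hits are discarded. The adaptive
ranking uses bitscores only — bitscores are direction-invariant, so the
ranking is identical whichever direction was actually computed; estimated
E-values enter only the threshold filter.

### Pseudo-reciprocal E-values

In pseudo mode only one direction per species pair is searched. The reverse
hit b→a inherits bitscore, identity and alignment length (all symmetric
quantities); its E-value is estimated as

    e = l · |Sₙ| / 2^bitscore

with l the length of b (the new query) and |Sₙ| the size of the original
query's species set (the new database). The implementation splits the
exponent (`ldexp` on the integer part) so the estimate is exact to ~1 ulp
for integer bitscores and underflows gradually to 0 for very large ones
instead of overflowing an intermediate. Estimated E-values face the same
`evalue_max` filter as computed ones, as drop-in replacements. On
jitter-free symmetric inputs pseudo and classic modes produce identical
edge sets (asserted in the test suite).

### Spectral decomposition

Groups are obtained by recursive bisection of each connected component.
For a component with n nodes and unweighted Laplacian L = D − A:

* its **normalized algebraic connectivity** is λ₂(L)/n, which is 1 exactly
  for complete graphs and in [0, 1] for every graph;
* if λ₂/n ≥ α (default 0.1) — or n ≤ 2 — the component is emitted as one
  group, annotated with that connectivity;
* otherwise it is split by the sign pattern of the Fiedler vector
  (negative entries vs the rest), each side is re-decomposed into connected
  pieces, and the recursion continues.

The normalization by n makes a single α meaningful across component sizes;
a raw-λ₂ threshold of 0.1 would essentially never split large dense
graphs. The Laplacian is unweighted: connectivity measures topology, while
bitscores are reserved for the flooding heuristic below. Both conventions
are isolated (`normalized_connectivity`, the Laplacian builder) so the
opposite choice is a one-line change.

**Solvers.** Components with n ≤ `dense_solver_max_n` (default 4096, at
which the dense matrix stays ~128 MB) use LAPACK's symmetric eigensolver
on the dense Laplacian. Larger components use a matrix-free power
iteration on the shifted operator cI − L with c = 2·max degree, which
keeps cI − L positive semidefinite with the Fiedler pair dominant once the
constant vector is deflated; the constant is projected out and the iterate
renormalized every step. Iteration stops when the eigen-residual
‖(cI − L)x − μx‖ ≤ `power_tol` (default 1e−7), which bounds the
*eigenvector* error by tol/gap — a Rayleigh-quotient-change criterion
would certify only the eigenvalue and leave sign decisions on small
Fiedler entries unreliable. Start vectors are drawn from a per-component
seed derived deterministically from the run seed and the component's
smallest node index, so results do not depend on scheduling.

**Numerical conventions.** Fiedler vectors are unit-norm, mean-free, and
sign-canonicalized by making the largest-magnitude entry positive (a
first-nonzero rule would let solver noise on structurally-zero entries
decide the global sign). In the bisection, entries within 1e−6 of zero
count as zero and join the non-negative side, and zero entries go to the
non-negative side; if one side comes out empty, the node with the most
extreme opposite entry is moved over so the recursion always progresses.
When λ₂ is degenerate (complete graphs, near-complete graphs with
symmetric missing-edge patterns) the Fiedler vector is not unique and the
two solvers may return different, equally valid bisections; the dual-solver
agreement test therefore compares bisections only where the spectral gap
λ₃ − λ₂ exceeds 1e−6.

### Flooding of oversized components

Components above `maxnodes` (default 32768) are first shrunk by removing
low-bitscore edges. Per round, edge bitscores are sorted ascending and the
minimum of the remaining scores is tested with a one-sided Grubbs outlier
test: G = (mean − min)/s (sample standard deviation), critical value
((n−1)/√n)·√(t²/(n−2+t²)) with t the upper (significance/n) quantile of
Student's t on n−2 df (significance default 0.05). While the minimum is a
significant low outlier it joins the removal batch and the test repeats on
the rest, so every batch is a prefix of the ascending score order — the
cutoff is raised until the significant outliers are covered. If no score
is significant, the lowest 1% of edges (at least one) is removed instead,
which guarantees termination. Nodes are never removed; components are
re-extracted after every round until all pieces fit. The prefix batch rule
is this package's reading of "raise a cutoff until a significant number of
outliers is covered"; it keeps the test's sample semantics approximately
valid between removals.

### Core mode

Core mode targets groups expected in *all* species of a component. The
connectivity threshold is ignored; a proposed Fiedler split is accepted
iff at least one side still covers every species of the **current**
component (evaluating coverage at the current recursion level rather than
the root avoids children that lost a species becoming unsplittable), and
recursion continues on both sides. When neither side preserves coverage
the component is emitted — unless its proteins-per-species ratio exceeds
`core_max_prots` (default 10), in which case it is deemed an inflated
mixture and split regardless. A side that does not itself cover all
species simply recurses under the same local rule.

## Parameters

| name | default | meaning |
|---|---|---|
| `evalue_max` | 1e−5 | hit E-value ceiling |
| `adaptive_factor` | 0.95 | near-best fraction f of the adaptive RBH rule |
| `min_identity_pct` | 25 | percent-identity floor |
| `min_coverage_pct` | 50 | coverage floor (shorter-protein denominator) |
| `alpha` | 0.1 | normalized connectivity (λ₂/n) acceptance threshold |
| `core_mode` / `core_max_prots` | off / 10 | species-coverage clustering and its size override |
| `maxnodes` | 32768 | flooding trigger size |
| `flood_significance` | 0.05 | Grubbs test level |
| `dense_solver_max_n` | 4096 | dense-vs-power solver crossover |
| `power_tol` / `power_max_iter` | 1e−7 / 100000 | power-iteration residual tolerance / cap |
| `seed` | 0 | root seed for solver start vectors |

The similarity thresholds (f, identity, coverage) follow the long-standing
defaults of reciprocal-best-hit practice; α, the E-value ceiling and
coreMaxProts are the established defaults of this family of methods;
`maxnodes` and `dense_solver_max_n` are this package's own desk-scale
choices and are exposed as parameters.

## Synthetic data

`simulate_component` reproduces the standard construction for clustering
benchmarks: a path over n nodes (guaranteeing connectivity), random edges
between currently unconnected pairs until ⌈density·n(n−1)/2⌉ edges exist,
bitscores uniform on [1, 2000] (drawn as reals so that score ties do not
dominate flooding behavior), E-values 1/bitscore. Density counts unordered
pairs.

`simulate_hit_tables` plants a known family partition: each family gets
1 + Poisson(mean−1) members per species (every family covers all species;
mean 1 gives exactly one member each), protein lengths uniform on
[100, 1000], within-family cross-species hits with bitscores uniform on
[300, 600] emitted in both directions (identical up to an optional
relative jitter), sparse background hits (rate 0.02 of cross-species
pairs, bitscores 10–50, single random direction), and E-values in *both*
directions from the analytic formula above — which is what makes
jitter-free fixtures behave identically under classic and pseudo modes.

What the generator does **not** emulate: realistic E-value statistics,
HSP fragmentation, compositional bias, domain-sharing between families,
within-species paralog hits, and incomplete family presence across
species. Passing tests therefore certify the graph algorithms and the
contracts between stages, not search-tool-specific behavior on real
proteomes.

With single-copy families each family forms an exact cross-species clique
in the RBH graph and the pipeline must recover the planted partition with
ARI 1.0; with multi-copy families within-family completeness is not
guaranteed by construction, so tests assert structural invariants rather
than exact recovery there.

## Determinism and parallelism

Worker parallelism is across connected components only; each component's
solver seed depends only on the run seed and the component's smallest node
index, and the final group list is sorted canonically (size descending,
then smallest member). Outputs are therefore byte-identical for any worker
count and across repeated runs at a fixed seed (asserted in the suite).

## Scale of the shipped experiments

The test suite and acceptance checks run at desk scale by design: simulated
components up to ~200 nodes (100 of them for the dual-solver comparison),
50 randomized brute-force comparisons for the RBH construction, 1000
rational-arithmetic checks of the E-value estimate, and 3-species
fixtures for end-to-end recovery. These sizes exercise every code path —
including flooding and the power solver, via lowered `maxnodes` and
`dense_solver_max_n` in tests — while keeping the default suite fast.

## Known limitations

* The ABC entry point assigns a single pseudo-species to plain node names
  (`species|protein` names carry labels), so core mode is only meaningful
  for labeled graphs.
* Flooding rebuilds components after each removal round rather than
  maintaining a dynamic connectivity structure; fine at desk scale,
  quadratic-ish in rounds for adversarial inputs.
* The dense solver materializes an n×n matrix; `dense_solver_max_n` should
  be lowered on memory-constrained machines.
* No attempt is made to recompute alignments or calibrate E-values beyond
  the analytic estimate; the package consumes whatever the search tool
  produced.
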