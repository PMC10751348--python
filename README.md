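# orthospect

Graph-based detection of (co-)orthologous protein groups across species.

Given all-vs-all protein similarity search results (the standard 12-column
tabular format) and the protein sets themselves (FASTA), `orthospect`

1. builds an **adaptive reciprocal best-hit graph**: a cross-species edge
   a–b exists iff b is among a's best hits against b's species *and* vice
   versa, where "best" includes every alternative hit whose bitscore reaches
   a fraction *f* (default 0.95) of the best one — this is what admits
   co-orthologs after lineage-specific duplications;
2. decomposes each connected component of that graph into groups by
   **recursive spectral clustering**: a component is accepted as a group
   once its normalized algebraic connectivity λ₂(L)/n (L = D − A the
   unweighted Laplacian) reaches a threshold α (default 0.1), and is
   otherwise bisected along the sign pattern of the Fiedler vector.

It is aimed at comparative genomics workflows that already have pairwise
search results and want orthologous-group calls — or at anyone who wants to
cluster an arbitrary weighted graph in ABC format by algebraic connectivity.

## Highlights

* **Pseudo-reciprocal mode** (default): only one search direction per
  species pair is required; the missing E-values are estimated as
  *e = l·|Sₙ| / 2^bitscore* from the query length *l*, database size |Sₙ|,
  and the (direction-symmetric) bitscore — halving the most expensive step
  of the whole analysis.
* Two interchangeable Fiedler solvers: a dense LAPACK path for components
  up to `dense_solver_max_n` nodes and a matrix-free **power iteration** on
  the edge list for larger ones.
* A **flooding heuristic** for components too large to solve: batches of
  low-bitscore outlier edges (one-sided Grubbs test) are removed until the
  pieces are tractable.
* A species-coverage driven **core mode** (`--core`) that splits groups
  only while one side still covers all species, for single-copy-ortholog
  style analyses.
* Scikit-learn-style estimators (`SpectralOrthoClustering`,
  `RbhGraphBuilder`) plus a CLI; a synthetic-data module generates
  components and multi-species hit fixtures with known ground truth.

## Worked example

Simulate a 3-species fixture with 4 planted single-copy families, then run
the end-to-end pipeline in pseudo-reciprocal mode (only the three forward
hit tables are passed):

```sh
orthospect simulate --fixture --species 3 --families 4 --seed 7 --out fixture
orthospect run \
    --fasta fixture/S1.fasta --fasta fixture/S2.fasta --fasta fixture/S3.fasta \
    --hits fixture/S1.vs.S2.tsv --hits fixture/S1.vs.S3.tsv --hits fixture/S2.vs.S3.tsv \
    --mode pseudo --out-groups groups.tsv --out-graph graph.abc --seed 1
```

```
INFO orthospect: read 12 proteins, 12 hits
INFO orthospect: graph: 12 nodes, 12 edges
INFO orthospect.cluster: clustered 4 components of 12 nodes into 4 groups
INFO orthospect: wrote 4 groups over 3 species to groups.tsv
```

`groups.tsv` (provenance headers omitted):

```
# Species	Genes	Alg.-Conn.	S1	S2	S3
3	3	1	f0m0	f0m0	f0m0
3	3	1	f1m0	f1m0	f1m0
3	3	1	f2m0	f2m0	f2m0
3	3	1	f3m0	f3m0	f3m0
```

Each row is one group: it covers 3 species with 3 proteins and was accepted
at normalized connectivity 1 (each family forms a complete triangle in the
reciprocal-best-hit graph); the remaining columns list the member protein
ids per species (`*` marks an absent species). The four recovered groups
are exactly the four planted families.

The same clustering is available for arbitrary graphs:

```sh
orthospect cluster graph.abc --out groups2.tsv --conn 0.1
```

and from Python:

```python
from orthospect import SpectralOrthoClustering, read_abc_graph

est = SpectralOrthoClustering(alpha=0.1).fit(read_abc_graph("graph.abc"))
est.labels_      # group index per node
est.groups_      # OrthoGroup objects with members and connectivity
```

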