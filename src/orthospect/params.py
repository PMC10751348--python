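"""Run parameters shared by the graph builder, the clustering drivers and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class ClusterParams:
    """All thresholds of a run, with the tool's default values.

    Parameters
    ----------
    evalue_max : float
        Upper E-value bound for a similarity hit to be considered.
    adaptive_factor : float
        Factor ``f`` in (0, 1]: besides the best hit, every hit whose bitscore
        reaches ``f * best`` is kept as an alternative (co-ortholog candidate).
    min_identity_pct : float
        Minimum percent identity of a hit.
    min_coverage_pct : float
        Minimum alignment coverage, 100 * aln_length / min(query len, subject len).
    alpha : float
        Normalized algebraic-connectivity threshold: a component whose
        lambda2 / n reaches ``alpha`` is accepted as one group.
    core_mode : bool
        Species-coverage driven clustering instead of the ``alpha`` threshold.
    core_max_prots : int
        In core mode, keep splitting while proteins-per-species exceeds this.
    maxnodes : int
        Components larger than this are decomposed by edge flooding before
        spectral clustering is attempted.
    flood_significance : float
        Significance level of the one-sided Grubbs outlier test used by flooding.
    dense_solver_max_n : int
        Components up to this size use the dense symmetric eigensolver;
        larger ones use the matrix-free power iteration.
    power_tol : float
        Convergence tolerance on the Rayleigh-quotient change per iteration.
    power_max_iter : int
        Iteration cap of the power method.
    seed : int
        Seed for every stochastic choice (power-iteration start vectors).
    """

    evalue_max: float = 1e-5
    adaptive_factor: float = 0.95
    min_identity_pct: float = 25.0
    min_coverage_pct: float = 50.0
    alpha: float = 0.1
    core_mode: bool = False
    core_max_prots: int = 10
    maxnodes: int = 32768
    flood_significance: float = 0.05
    dense_solver_max_n: int = 4096
    power_tol: float = 1e-7
    power_max_iter: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.adaptive_factor <= 1.0):
            raise ValueError("adaptive_factor must be in (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.core_max_prots < 1 or self.maxnodes < 1:
            raise ValueError("core_max_prots and maxnodes must be positive")

    def as_header_items(self) -> list[tuple[str, object]]:
        """Stable (name, value) list for provenance headers."""
        return [(f.name, getattr(self, f.name)) for f in fields(self)]

    def component_seed(self, min_node_index: int) -> int:
        """Deterministic per-component seed below 2**31.

        Depends only on the run seed and the component's smallest global node
        index, so results are identical for any worker count or visit order.
        """
        return (self.seed * 1_000_003 + 0x9E3779B1 * (min_node_index + 1)) % (2**31)
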