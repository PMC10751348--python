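"""Algebraic connectivity and Fiedler vectors of connected components.

Two interchangeable solvers compute the second-smallest eigenvalue lambda2
of the unweighted graph Laplacian L = D - A together with its eigenvector
(the Fiedler vector):

* a dense symmetric eigensolver (LAPACK, via :func:`scipy.linalg.eigh`) for
  components small enough to afford an n x n matrix, and
* a matrix-free power iteration on the shifted operator cI - L with
  c = 2 * max degree, which only ever touches the edge list.

The Fiedler vector's sign pattern defines the spectral bisection used by the
clustering drivers.  Connectivity is normalized as lambda2 / n, which equals
1 for complete graphs and lies in [0, 1] for every graph, so a single
threshold is comparable across component sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .graph import ConnectedComponent


class PowerIterationError(RuntimeError):
    """Power iteration failed to converge; carries the last estimate."""

    def __init__(self, message: str, last_estimate: float) -> None:
        super().__init__(message)
        self.last_estimate = last_estimate


@dataclass(frozen=True)
class FiedlerResult:
    """Eigenpair (lambda2, Fiedler vector) of a component's Laplacian."""

    lambda2: float
    vector: np.ndarray  # unit norm, orthogonal to the constant vector
    solver: str  # "dense" | "power"
    iterations: int = 0


def _edge_arrays(component: ConnectedComponent) -> tuple[np.ndarray, np.ndarray]:
    """Local endpoint index arrays of the component's edge list."""
    local = component.local_index()
    m = component.m
    lu = np.empty(m, dtype=np.intp)
    lv = np.empty(m, dtype=np.intp)
    for i, (u, v, _w) in enumerate(component.edges):
        lu[i] = local[u]
        lv[i] = local[v]
    return lu, lv


def _apply_edges(lu: np.ndarray, lv: np.ndarray, x: np.ndarray) -> np.ndarray:
    """L @ x in one pass over the edge endpoint arrays."""
    y = np.zeros_like(x)
    d = x[lu] - x[lv]
    np.add.at(y, lu, d)
    np.subtract.at(y, lv, d)
    return y


def laplacian_apply(component: ConnectedComponent, x: np.ndarray) -> np.ndarray:
    """Matrix-free product L @ x over the edge list (unweighted Laplacian)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (component.n,):
        raise ValueError("vector length must equal the component size")
    lu, lv = _edge_arrays(component)
    return _apply_edges(lu, lv, x)


def _dense_laplacian(component: ConnectedComponent) -> np.ndarray:
    local = component.local_index()
    lap = np.zeros((component.n, component.n))
    for u, v, _w in component.edges:
        lu, lv = local[u], local[v]
        lap[lu, lv] -= 1.0
        lap[lv, lu] -= 1.0
        lap[lu, lu] += 1.0
        lap[lv, lv] += 1.0
    return lap


#: entries this close to zero are treated as exact zeros when the sign
#: pattern is read off (well below any meaningful Fiedler entry, above the
#: numerical noise both solvers leave on structurally-zero entries)
ZERO_ENTRY_TOL = 1e-6


def _finalize(vec: np.ndarray) -> np.ndarray:
    vec = vec - vec.mean()
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
    # canonical global sign: largest-magnitude entry positive (robust to
    # solver noise on near-zero entries)
    if vec[int(np.argmax(np.abs(vec)))] < 0:
        vec = -vec
    return vec


def fiedler_dense(
    component: ConnectedComponent, max_n: int = 4096
) -> FiedlerResult:
    """Fiedler pair via the dense symmetric eigensolver.

    Builds the full Laplacian, so it is restricted to components with
    ``n <= max_n``; larger components must use :func:`fiedler_power`.
    """
    if component.n > max_n:
        raise ValueError(
            f"component of size {component.n} exceeds the dense-solver cap "
            f"{max_n}; use the power iteration"
        )
    if component.n < 2:
        raise ValueError("Fiedler pair requires at least 2 nodes")
    lap = _dense_laplacian(component)
    vals, vecs = scipy.linalg.eigh(lap, subset_by_index=[0, 1])
    return FiedlerResult(
        lambda2=float(vals[1]), vector=_finalize(vecs[:, 1]), solver="dense"
    )


def fiedler_power(
    component: ConnectedComponent,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    seed: int = 0,
) -> FiedlerResult:
    """Fiedler pair via power iteration on the shifted operator cI - L.

    The shift c = 2 * max degree makes cI - L positive semidefinite with the
    Fiedler pair dominant once the constant vector is deflated: the constant
    vector is projected out and the iterate renormalized every step.  The
    iteration stops when the eigen-residual ||(cI - L) x - mu x|| drops to
    ``tol`` (mu the Rayleigh quotient of cI - L), which bounds the
    eigenvector error by tol / gap and keeps the sign pattern reliable, not
    just the eigenvalue.  lambda2 is recovered as c minus the converged
    quotient.
    """
    n = component.n
    if n < 2:
        raise ValueError("Fiedler pair requires at least 2 nodes")
    deg = component.degrees()
    c = 2.0 * max(deg)
    lu, lv = _edge_arrays(component)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x -= x.mean()
    x /= np.linalg.norm(x)
    mu = np.inf
    for it in range(1, max_iter + 1):
        y = c * x - _apply_edges(lu, lv, x)
        y -= y.mean()
        norm = np.linalg.norm(y)
        if norm < 1e-200:
            # x spans the kernel of cI - L: lambda2 equals the shift exactly
            return FiedlerResult(
                lambda2=c, vector=_finalize(x), solver="power", iterations=it
            )
        x = y / norm
        op = c * x - _apply_edges(lu, lv, x)
        mu = float(x @ op)
        if np.linalg.norm(op - mu * x) <= tol:
            return FiedlerResult(
                lambda2=c - mu,
                vector=_finalize(x),
                solver="power",
                iterations=it,
            )
    raise PowerIterationError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(component size {n})",
        last_estimate=c - mu,
    )


def solve_fiedler(
    component: ConnectedComponent,
    dense_solver_max_n: int = 4096,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    seed: int = 0,
) -> FiedlerResult:
    """Dispatch to the dense solver for small components, else power iteration."""
    if component.n <= dense_solver_max_n:
        return fiedler_dense(component, max_n=dense_solver_max_n)
    return fiedler_power(component, tol=tol, max_iter=max_iter, seed=seed)


def normalized_connectivity(
    component: ConnectedComponent, fiedler: FiedlerResult | None
) -> float:
    """lambda2 / n: 1 for complete graphs, in [0, 1] generally.

    Singletons return 1 by convention (``fiedler`` may be None for them).
    """
    if component.n <= 1:
        return 1.0
    if fiedler is None:
        raise ValueError("a Fiedler result is required for n >= 2")
    return fiedler.lambda2 / component.n


def bisect(
    component: ConnectedComponent, fiedler: FiedlerResult
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Split a component by the Fiedler vector's sign pattern.

    Side A collects nodes with negative entries, side B the rest (zero
    entries go to B; entries within ``ZERO_ENTRY_TOL`` of zero count as
    zero, so solver noise on structurally-zero entries cannot decide a
    side).  If one side comes out empty — possible for degenerate sign
    patterns — the single node with the most extreme entry of the opposite
    tendency is moved over so that the bisection always makes progress.
    Returns global node indices.
    """
    if component.n < 2:
        raise ValueError("cannot bisect fewer than 2 nodes")
    vec = fiedler.vector
    nodes = np.asarray(component.node_indices)
    neg = vec < -ZERO_ENTRY_TOL
    if not neg.any():
        neg[int(np.argmin(vec))] = True
    elif neg.all():
        neg[int(np.argmax(vec))] = False
    side_a = tuple(int(g) for g in nodes[neg])
    side_b = tuple(int(g) for g in nodes[~neg])
    return side_a, side_b
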