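"""Decomposition of oversized components by outlier-edge removal.

Components too large for spectral clustering are broken up by iteratively
deleting batches of unusually low-bitscore edges.  In each round the edge
bitscores are sorted ascending and the running minimum of the remaining
scores is tested with a one-sided Grubbs outlier test; while the minimum is
a significant low outlier it is added to the removal batch and the test is
repeated on the rest, so each batch is a prefix of the ascending score
order.  If no score is a significant outlier, the lowest 1% of edges (at
least one) is removed instead so that the procedure always terminates.
Nodes are never removed: the union of the returned components' node sets
equals the input node set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .graph import ConnectedComponent, components_from_edges
from .params import ClusterParams

log = logging.getLogger(__name__)


class FloodingError(RuntimeError):
    """A component stayed above the size bound with no removable edge left."""


@dataclass(frozen=True)
class GrubbsDecision:
    """Outcome of a one-sided (minimum-directed) Grubbs outlier test."""

    statistic: float  # G = (mean - min) / s; NaN when not testable
    critical_value: float  # NaN when not testable
    n: int
    is_outlier: bool
    testable: bool = True


def grubbs_min_test(values, significance: float = 0.05) -> GrubbsDecision:
    """Test whether the minimum of ``values`` is a low outlier.

    G = (mean - min) / s with the sample standard deviation s; the critical
    value is G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) where t is
    the upper significance/n quantile of Student's t on n-2 degrees of
    freedom.  Samples with n < 3 or zero variance are not testable and are
    reported as no-outlier.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 3:
        return GrubbsDecision(math.nan, math.nan, n, False, testable=False)
    sd = arr.std(ddof=1)
    if sd == 0.0:
        return GrubbsDecision(math.nan, math.nan, n, False, testable=False)
    g = (arr.mean() - arr.min()) / sd
    t = stats.t.ppf(1.0 - significance / n, n - 2)
    g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
    return GrubbsDecision(float(g), float(g_crit), n, bool(g > g_crit))


def _removal_batch_size(scores: np.ndarray, significance: float) -> int:
    """Length of the ascending-order prefix flagged as low outliers."""
    k = 0
    while scores.size - k >= 3:
        if grubbs_min_test(scores[k:], significance).is_outlier:
            k += 1
        else:
            break
    return k


def flood(
    component: ConnectedComponent, params: ClusterParams | None = None
) -> list[ConnectedComponent]:
    """Split a component into pieces of at most ``params.maxnodes`` nodes.

    Components already within the bound are returned unchanged.  Edge
    bitscores are the removal criterion; see the module docstring for the
    batch rule.
    """
    params = params or ClusterParams()
    if component.n <= params.maxnodes:
        return [component]
    done: list[ConnectedComponent] = []
    queue = [component]
    while queue:
        comp = queue.pop()
        if comp.n <= params.maxnodes:
            done.append(comp)
            continue
        if comp.m == 0:
            raise FloodingError(
                f"component of size {comp.n} exceeds maxnodes="
                f"{params.maxnodes} but has no removable edges"
            )
        # deterministic ascending order: bitscore, then endpoint indices
        edges = sorted(comp.edges, key=lambda e: (e[2], e[0], e[1]))
        scores = np.array([e[2] for e in edges])
        k = _removal_batch_size(scores, params.flood_significance)
        if k == 0:
            k = max(1, comp.m // 100)
            log.info(
                "flooding: no significant outlier among %d edges; "
                "removing the lowest %d by bitscore",
                comp.m,
                k,
            )
        else:
            log.info(
                "flooding: removing %d outlier edges (of %d) with bitscore "
                "<= %g",
                k,
                comp.m,
                edges[k - 1][2],
            )
        queue.extend(components_from_edges(comp, edges[k:]))
    done.sort(key=lambda c: (-c.n, c.node_indices[0]))
    return done
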