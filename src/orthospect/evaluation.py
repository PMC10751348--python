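"""Comparison metrics: edge-set sensitivity/precision, adjusted Rand index,
and the mean-log2-fold improvement aggregate.

Sensitivity and precision treat one edge set as the reference: with
TP = |test ∩ ref|, FP = |test \\ ref|, FN = |ref \\ test|,
sensitivity = TP/(TP+FN) and precision = TP/(TP+FP).  Undefined ratios
(empty denominators) are surfaced as ``None`` rather than silently zeroed.

The adjusted Rand index is the chance-corrected agreement between two
partitions of the same element set, computed from the contingency table.

``improvement`` summarizes paired benchmark scores as the mean log2 fold
ratio, oriented so that positive values always mean the test run is better;
a mean of 0.5 corresponds to scores that are on average 2**0.5 - 1 ≈ 41%
better than the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence


@dataclass(frozen=True)
class EdgeSetMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None


def _canonical(edges: Iterable[tuple]) -> set[tuple]:
    out = set()
    for a, b in edges:
        out.add((a, b) if a <= b else (b, a))
    return out


def edge_set_metrics(test_edges: Iterable, ref_edges: Iterable) -> EdgeSetMetrics:
    """Count shared and exclusive edges between two undirected edge sets."""
    test = _canonical(test_edges)
    ref = _canonical(ref_edges)
    tp = len(test & ref)
    return EdgeSetMetrics(tp=tp, fp=len(test) - tp, fn=len(ref) - tp)


def _as_labels(partition) -> dict[Hashable, int]:
    if isinstance(partition, Mapping):
        uniq = {lab: i for i, lab in enumerate(dict.fromkeys(partition.values()))}
        return {el: uniq[lab] for el, lab in partition.items()}
    labels: dict[Hashable, int] = {}
    for i, block in enumerate(partition):
        for el in block:
            if el in labels:
                raise ValueError(f"element {el!r} appears in two blocks")
            labels[el] = i
    return labels


def adjusted_rand_index(partition_p, partition_q) -> float:
    """Chance-corrected partition agreement from the contingency table.

    Partitions may be given as iterables of disjoint blocks or as
    element-to-label mappings; both must cover the same element set.
    Identical partitions score 1; the expected score of independent random
    partitions is 0.
    """
    p = _as_labels(partition_p)
    q = _as_labels(partition_q)
    if p.keys() != q.keys():
        raise ValueError("partitions must cover the same element set")
    n = len(p)
    if n == 0:
        raise ValueError("partitions must be non-empty")

    contingency: dict[tuple[int, int], int] = {}
    row: dict[int, int] = {}
    col: dict[int, int] = {}
    for el, pi in p.items():
        qi = q[el]
        contingency[(pi, qi)] = contingency.get((pi, qi), 0) + 1
        row[pi] = row.get(pi, 0) + 1
        col[qi] = col.get(qi, 0) + 1

    def c2(k: int) -> int:
        return k * (k - 1) // 2

    index = sum(c2(v) for v in contingency.values())
    sum_row = sum(c2(v) for v in row.values())
    sum_col = sum(c2(v) for v in col.values())
    total = c2(n)
    expected = sum_row * sum_col / total if total else 0.0
    max_index = (sum_row + sum_col) / 2.0
    if max_index == expected:  # both partitions trivial (all-singletons etc.)
        return 1.0 if index == expected else 0.0
    return (index - expected) / (max_index - expected)


def improvement(
    test_scores: Sequence[float],
    baseline_scores: Sequence[float],
    higher_is_better: bool | Sequence[bool] = True,
) -> float:
    """Mean log2 fold ratio of paired scores, oriented per metric.

    For higher-is-better metrics the ratio is test/baseline, for
    lower-is-better metrics baseline/test, so positive output always means
    the test run outperforms the baseline.  All scores must be positive.
    """
    if len(test_scores) != len(baseline_scores) or not test_scores:
        raise ValueError("need equally many (>=1) test and baseline scores")
    if isinstance(higher_is_better, bool):
        orient: Sequence[bool] = [higher_is_better] * len(test_scores)
    else:
        orient = higher_is_better
        if len(orient) != len(test_scores):
            raise ValueError("one orientation flag per score pair required")
    total = 0.0
    for t, b, hib in zip(test_scores, baseline_scores, orient):
        if t <= 0 or b <= 0:
            raise ValueError("scores must be strictly positive")
        ratio = t / b if hib else b / t
        total += math.log2(ratio)
    return total / len(test_scores)


def improvement_to_percent(mean_log2_fold: float) -> float:
    """Percent score gain implied by a mean log2 fold ratio."""
    return (2.0**mean_log2_fold - 1.0) * 100.0
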