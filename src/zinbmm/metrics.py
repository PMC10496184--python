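"""Evaluation metrics: adjusted Rand index and gene-selection scores.

The ARI is computed from the four pair counts over all C(n, 2) cell pairs —
agreeing-same, agreeing-different, and the two disagreement types — which
reproduces the standard chance-corrected index. Gene selection is scored by
Recall / Precision / F1 against the known informative-gene flags, and
replicate scores are summarised as median and (raw, unscaled) median absolute
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PairCounts:
    """Pair-level agreement counts between two partitions of n items.

    a: same cluster in both; b: different in both;
    c: same in truth, different in estimate; d: same in estimate, different
    in truth. a + b + c + d = C(n, 2).
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SelectionCounts:
    TP: int
    FP: int
    FN: int


def _comb2(x):
    return x * (x - 1) // 2


def pair_counts(truth, estimate) -> PairCounts:
    """Pair counts via the contingency table (O(n + #cells of the table))."""
    truth = np.asarray(truth)
    estimate = np.asarray(estimate)
    if truth.shape != estimate.shape or truth.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = truth.size
    if n < 2:
        raise ValueError("need at least two items")
    _, ti = np.unique(truth, return_inverse=True)
    _, ei = np.unique(estimate, return_inverse=True)
    table = np.zeros((ti.max() + 1, ei.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, ei), 1)
    a = int(_comb2(table).sum())
    same_truth = int(_comb2(table.sum(axis=1)).sum())   # a + c
    same_est = int(_comb2(table.sum(axis=0)).sum())     # a + d
    total = int(_comb2(n))
    c = same_truth - a
    d = same_est - a
    b = total - a - c - d
    return PairCounts(a=a, b=b, c=c, d=d)


def ari(truth, estimate) -> float:
    """Adjusted Rand index in [-1, 1]; 1 means identical partitions."""
    pc = pair_counts(truth, estimate)
    total = pc.total
    same_truth = pc.a + pc.c
    same_est = pc.a + pc.d
    expected = same_truth * same_est / total
    max_index = 0.5 * (same_truth + same_est)
    if max_index == expected:  # both partitions trivial
        return 1.0 if pc.c == 0 and pc.d == 0 else 0.0
    return float((pc.a - expected) / (max_index - expected))


def selection_counts(truth_flags, selected_set) -> SelectionCounts:
    truth_flags = np.asarray(truth_flags, dtype=bool)
    selected = np.asarray(selected_set, dtype=bool)
    if selected.shape != truth_flags.shape:
        raise ValueError("flags and selection must cover the same gene universe")
    tp = int(np.sum(truth_flags & selected))
    fp = int(np.sum(~truth_flags & selected))
    fn = int(np.sum(truth_flags & ~selected))
    return SelectionCounts(TP=tp, FP=fp, FN=fn)


def selection_prf(truth_flags, selected_flags):
    """(Recall, Precision, F1) of a gene selection against the true flags.

    An empty selection scores Precision 0 by convention; F1 is 0 whenever
    Precision + Recall is 0.
    """
    sc = selection_counts(truth_flags, selected_flags)
    recall = sc.TP / (sc.TP + sc.FN) if sc.TP + sc.FN else 0.0
    precision = sc.TP / (sc.TP + sc.FP) if sc.TP + sc.FP else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return recall, precision, f1


def replicate_summary(values):
    """(median, raw MAD) of per-replicate scores."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one replicate value")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, mad
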