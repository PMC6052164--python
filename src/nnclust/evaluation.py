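"""External clustering evaluation: macro-averaged F-score.

Clusters carry arbitrary labels, so scoring against ground truth requires a
cluster-to-class matching. Two conventions are provided:

* ``optimal_one_to_one`` (default) — the one-to-one class/cluster matching
  maximizing the summed per-class F1, found by assignment optimization on
  the class-by-cluster F1 matrix. Classes left unmatched (when K < C) score
  0; surplus clusters are ignored. This convention penalizes cluster
  collapse: putting everything in one cluster cannot score near 1.
* ``best_match_per_class`` — each class independently takes the cluster
  maximizing its F1 (clusters may be reused).

The macro F is the unweighted mean of per-class F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ContingencyTable",
    "FScoreReport",
    "contingency_table",
    "pair_f_score",
    "macro_f_score",
]

MATCHING_CONVENTIONS = ("optimal_one_to_one", "best_match_per_class")


@dataclass(frozen=True)
class ContingencyTable:
    """counts[c, k] = number of samples with true class c in cluster k."""

    counts: npt.NDArray[np.int64]
    class_labels: tuple
    cluster_labels: tuple

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FScoreReport:
    per_class_f: npt.NDArray[np.float64]
    macro_f: float
    mapping: dict  # class label -> matched cluster label (partial, one-to-one for optimal)
    table: ContingencyTable
    matching: str


def contingency_table(truth, pred, K: int | None = None) -> ContingencyTable:
    """Cross-tabulate true class labels against predicted cluster labels.

    Class/cluster identities are the sorted distinct values observed; pass
    ``K`` to declare extra (empty) integer cluster columns 0..K-1.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError(
            f"truth and pred must be equal-length vectors, got {truth.shape} and {pred.shape}"
        )
    if truth.size < 1:
        raise ValueError("need at least one sample")
    classes, truth_idx = np.unique(truth, return_inverse=True)
    if K is not None:
        clusters = np.arange(K)
        pred_idx = np.asarray(pred, dtype=np.int64)
        if pred_idx.min() < 0 or pred_idx.max() >= K:
            raise ValueError(f"pred labels out of declared range [0, {K})")
    else:
        clusters, pred_idx = np.unique(pred, return_inverse=True)
    counts = np.zeros((classes.size, clusters.size), dtype=np.int64)
    np.add.at(counts, (truth_idx, pred_idx), 1)
    return ContingencyTable(
        counts=counts,
        class_labels=tuple(classes.tolist()),
        cluster_labels=tuple(clusters.tolist()),
    )


def pair_f_score(table: ContingencyTable, class_index: int, cluster_index: int) -> float:
    """F1 of treating cluster k as the predicted positive set for class c.

    precision = counts[c,k] / column sum, recall = counts[c,k] / row sum,
    F = 2PR/(P+R) with F = 0 when P + R = 0.
    """
    tp = table.counts[class_index, cluster_index]
    col = table.counts[:, cluster_index].sum()
    row = table.counts[class_index, :].sum()
    if tp == 0:
        return 0.0
    precision = tp / col
    recall = tp / row
    return float(2 * precision * recall / (precision + recall))


def _pair_f_matrix(table: ContingencyTable) -> npt.NDArray[np.float64]:
    counts = table.counts.astype(np.float64)
    col = counts.sum(axis=0, keepdims=True)
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, counts / col, 0.0)
        recall = np.where(row > 0, counts / row, 0.0)
        denom = precision + recall
        f = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return f


def macro_f_score(truth, pred, matching: str = "optimal_one_to_one") -> FScoreReport:
    """Macro-averaged F-score of a clustering against ground-truth classes."""
    if matching not in MATCHING_CONVENTIONS:
        raise ValueError(
            f"unknown matching {matching!r}; choose from {MATCHING_CONVENTIONS}"
        )
    table = contingency_table(truth, pred)
    f = _pair_f_matrix(table)
    C, K = f.shape

    if matching == "optimal_one_to_one":
        rows, cols = linear_sum_assignment(f, maximize=True)
        per_class = np.zeros(C)
        mapping = {}
        for c, k in zip(rows, cols):
            per_class[c] = f[c, k]
            mapping[table.class_labels[c]] = table.cluster_labels[k]
    else:
        best = f.argmax(axis=1)
        per_class = f[np.arange(C), best]
        mapping = {
            table.class_labels[c]: table.cluster_labels[best[c]] for c in range(C)
        }

    return FScoreReport(
        per_class_f=per_class,
        macro_f=float(per_class.mean()),
        mapping=mapping,
        table=table,
        matching=matching,
    )
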