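"""Binary-classification performance measures for cleavage prediction.

Cleavage is the positive class (+1).  Accuracy, sensitivity and
specificity are reported as percentages; the Matthews correlation
coefficient (MCC) is the class-imbalance-robust correlation between
predicted and true labels; AUC is the rank-based (Mann-Whitney) area
under the ROC curve, with tied scores counted half.

Undefined rates (zero denominator) yield ``None`` rather than an
exception; the MCC of a degenerate confusion matrix is 0 by convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "mcc",
    "auc",
    "report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Acc/Sen/Spe in percent; MCC in [-1, 1]; AUC in [0, 1]."""

    mcc: float
    auc: float | None
    acc: float | None
    sen: float | None
    spe: float | None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"MCC": self.mcc, "AUC": self.auc, "Acc": self.acc,
                 "Sen": self.sen, "Spe": self.spe},
                fh, indent=2,
            )
            fh.write("\n")

    def to_tsv(self, path) -> None:
        """One-row TSV in the conventional column order MCC, AUC, Acc, Sen, Spe."""
        def fmt(v, nd):
            return "NA" if v is None else f"{v:.{nd}f}"

        with open(path, "w") as fh:
            fh.write("MCC\tAUC\tAcc\tSen\tSpe\n")
            fh.write(
                "\t".join(
                    [fmt(self.mcc, 4), fmt(self.auc, 4), fmt(self.acc, 2),
                     fmt(self.sen, 2), fmt(self.spe, 2)]
                )
                + "\n"
            )


def _check_labels(labels: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(labels)
    if not np.isin(arr, (-1, 1)).all():
        raise ValueError(f"{name} must take values in {{+1, -1}}")
    return arr


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionCounts:
    """Cross-tabulate +1/-1 labels with cleavage (+1) as the positive class."""
    y = _check_labels(true_labels, "true_labels")
    p = _check_labels(predicted_labels, "predicted_labels")
    if y.shape != p.shape:
        raise ValueError("label sequences differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == -1) & (p == 1))),
        tn=int(np.sum((y == -1) & (p == -1))),
        fn=int(np.sum((y == 1) & (p == -1))),
    )


def accuracy(c: ConfusionCounts) -> float | None:
    """100 * (TP + TN) / total, or None on an empty table."""
    return None if c.total == 0 else 100.0 * (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float | None:
    """100 * TP / (TP + FN): fraction of true cleavage sites recovered."""
    d = c.tp + c.fn
    return None if d == 0 else 100.0 * c.tp / d


def specificity(c: ConfusionCounts) -> float | None:
    """100 * TN / (TN + FP): fraction of non-cleavage sites recovered."""
    d = c.tn + c.fp
    return None if d == 0 else 100.0 * c.tn / d


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def auc(true_labels: Sequence[int], scores: Sequence[float]) -> float | None:
    """Mann-Whitney AUC: P(random positive outscores random negative).

    Ties count one half.  Returns None when only one class is present.
    """
    y = _check_labels(true_labels, "true_labels")
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)  # midranks implement the half-tie convention
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def report(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """Full metrics from labels, predictions and (optionally) decision values."""
    c = confusion(true_labels, predicted_labels)
    return MetricsReport(
        mcc=mcc(c),
        auc=None if scores is None else auc(true_labels, scores),
        acc=accuracy(c),
        sen=sensitivity(c),
        spe=specificity(c),
    )
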