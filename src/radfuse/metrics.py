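"""Classification metrics: confusion counts, accuracy/sensitivity/specificity, AUC.

Multi-class sensitivity and specificity are macro-averaged over one-vs-rest
confusion tables; AUC is the rank statistic (probability a random positive
outranks a random negative, ties at 1/2), macro one-vs-rest for more than two
classes.  Degenerate denominators (e.g. specificity with no negatives) yield
NaN as an "undefined" flag rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "metrics_from_confusion",
    "auc_score",
    "evaluate_predictions",
]


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion table."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int) -> list[ConfusionCounts]:
    """Per-class one-vs-rest confusion counts."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    tables = []
    for c in range(n_classes):
        pos, hit = y_true == c, y_pred == c
        tables.append(
            ConfusionCounts(
                tp=int(np.sum(pos & hit)),
                tn=int(np.sum(~pos & ~hit)),
                fp=int(np.sum(~pos & hit)),
                fn=int(np.sum(pos & ~hit)),
            )
        )
    return tables


def metrics_from_confusion(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN flags an undefined ratio."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    acc = (c.tp + c.tn) / c.total
    sen = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    spe = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    return acc, sen, spe


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Binary ranking AUC (Mann-Whitney normalisation, ties count 1/2).

    Returns NaN when only one class is present.
    """
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, scores))


@dataclass
class MetricsReport:
    acc: float
    auc: float
    sen: float
    spe: float
    per_class: pd.DataFrame
    confusion: np.ndarray  # n_classes x n_classes counts, rows = truth

    def normalized_confusion(self) -> np.ndarray:
        row_sums = self.confusion.sum(axis=1, keepdims=True)
        return self.confusion / np.maximum(row_sums, 1)


def evaluate_predictions(y_true: np.ndarray, prob: np.ndarray) -> MetricsReport:
    """Full report from true labels and per-class probability scores."""
    y_true = np.asarray(y_true)
    prob = np.asarray(prob, float)
    if prob.ndim != 2:
        raise ValueError("prob must be (n_samples, n_classes)")
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    n_classes = prob.shape[1]
    y_pred = prob.argmax(axis=1)
    acc = float(np.mean(y_pred == y_true))

    rows = []
    for c, table in enumerate(confusion_counts(y_true, y_pred, n_classes)):
        _, sen_c, spe_c = metrics_from_confusion(table)
        auc_c = auc_score(prob[:, c], (y_true == c).astype(int))
        rows.append(
            {"class": c, "tp": table.tp, "tn": table.tn, "fp": table.fp,
             "fn": table.fn, "sen": sen_c, "spe": spe_c, "auc": auc_c}
        )
    per_class = pd.DataFrame(rows)

    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[t, p] += 1

    if n_classes == 2:
        # binary convention: class 1 is the positive class
        _, sen, spe = metrics_from_confusion(
            confusion_counts(y_true, y_pred, 2)[1]
        )
        auc = auc_score(prob[:, 1], (y_true == 1).astype(int))
    else:
        sen = float(np.nanmean(per_class["sen"]))
        spe = float(np.nanmean(per_class["spe"]))
        auc = float(np.nanmean(per_class["auc"]))

    return MetricsReport(acc=acc, auc=auc, sen=float(sen), spe=float(spe),
                         per_class=per_class, confusion=confusion)
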