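"""Scoring of stacking predictions.

Two junction-level metrics are reported: exact full-configuration accuracy
(a prediction counts only if the complete set of stacked pairs matches the
annotation), the headline metric for junctions below order five, and
pairwise accuracy (PA) -- the fraction of cyclically adjacent stem pairs
whose stacked/unstacked status is correct -- which stays tractable for
higher orders.  Standard binary metrics (accuracy, precision, recall, F1,
AUC, Cohen's kappa) and confusion matrices cover the per-pair classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .reconstruction import StackingConfiguration, configuration_label, cycle_edges

__all__ = [
    "ConfusionMatrix",
    "BinaryMetrics",
    "configuration_accuracy",
    "pairwise_accuracy",
    "mean_pairwise_accuracy",
    "binary_metrics",
    "configuration_confusion",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("negative confusion counts")
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts shape must match label count")


@dataclass(frozen=True)
class BinaryMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: Optional[float]
    kappa: float
    confusion: ConfusionMatrix

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "kappa": self.kappa,
            "confusion": self.confusion.counts.tolist(),
        }


def _check_aligned(
    predictions: Sequence[StackingConfiguration],
    truths: Sequence[StackingConfiguration],
) -> None:
    if len(predictions) != len(truths):
        raise ValueError("prediction/truth lists differ in length")
    for p, t in zip(predictions, truths):
        if p.junction_id != t.junction_id or p.order_n != t.order_n:
            raise ValueError(f"misaligned junctions: {p.junction_id} vs {t.junction_id}")


def configuration_accuracy(
    predictions: Sequence[StackingConfiguration],
    truths: Sequence[StackingConfiguration],
) -> float:
    """Fraction of junctions whose predicted stack set matches exactly.

    One spurious or missing stack makes the whole junction wrong.  Intended
    for orders below five; a warning is issued for higher orders, where PA
    is the customary metric.
    """
    _check_aligned(predictions, truths)
    if not predictions:
        raise ValueError("empty prediction list")
    if any(p.order_n >= 5 for p in predictions):
        warnings.warn("configuration accuracy on order >= 5 junctions; PA is customary")
    hits = sum(p.stacked_pairs == t.stacked_pairs for p, t in zip(predictions, truths))
    return hits / len(predictions)


def pairwise_accuracy(
    prediction: StackingConfiguration, truth: StackingConfiguration
) -> float:
    """PA: fraction of cyclically adjacent pairs with correct stacked status."""
    if prediction.order_n != truth.order_n or prediction.junction_id != truth.junction_id:
        raise ValueError("prediction and truth must describe the same junction")
    edges = cycle_edges(truth.order_n)
    correct = sum(
        (e in prediction.stacked_pairs) == (e in truth.stacked_pairs) for e in edges
    )
    return correct / len(edges)


def mean_pairwise_accuracy(
    predictions: Sequence[StackingConfiguration],
    truths: Sequence[StackingConfiguration],
    mode: str = "macro",
) -> float:
    """Average PA over junctions: per-junction then averaged (``macro``,
    default) or pooled over all adjacent pairs (``pooled``)."""
    _check_aligned(predictions, truths)
    if not predictions:
        raise ValueError("empty prediction list")
    if mode == "macro":
        return float(np.mean([pairwise_accuracy(p, t) for p, t in zip(predictions, truths)]))
    if mode == "pooled":
        num = den = 0
        for p, t in zip(predictions, truths):
            edges = cycle_edges(t.order_n)
            num += sum((e in p.stacked_pairs) == (e in t.stacked_pairs) for e in edges)
            den += len(edges)
        return num / den
    raise ValueError("mode must be 'macro' or 'pooled'")


def binary_metrics(
    labels: Sequence[int],
    probabilities: Sequence[float],
    threshold: float,
) -> BinaryMetrics:
    """Full binary metric suite at a probability threshold.

    AUC is the rank statistic over probabilities; with a single observed
    class it is reported as undefined (None), not 0.5.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(y) == 0 or len(y) != len(p):
        raise ValueError("labels and probabilities must be aligned and nonempty")
    pred = (p > threshold).astype(int)
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else None
    cm = confusion_matrix(y, pred, labels=[0, 1])
    return BinaryMetrics(
        accuracy=float(accuracy_score(y, pred)),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)),
        auc=auc,
        kappa=float(cohen_kappa_score(y, pred)),
        confusion=ConfusionMatrix(labels=("unstacked", "stacked"), counts=cm),
    )


def configuration_confusion(
    predictions: Sequence[StackingConfiguration],
    truths: Sequence[StackingConfiguration],
) -> ConfusionMatrix:
    """Configuration-level confusion matrix in H_i-H_j notation."""
    _check_aligned(predictions, truths)
    names = sorted(
        {configuration_label(c) for c in predictions} | {configuration_label(c) for c in truths}
    )
    index = {n: i for i, n in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=int)
    for p, t in zip(predictions, truths):
        counts[index[configuration_label(t)], index[configuration_label(p)]] += 1
    return ConfusionMatrix(labels=tuple(names), counts=counts)
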