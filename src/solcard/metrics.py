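"""Classification metrics entering the optimizer fitness and the run logs.

The positive class is soluble throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from scipy import stats

from .seq_io import SOLUBLE

__all__ = ["roc_auc", "confusion_metrics", "pearson_r", "FitnessResult"]


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return np.array([1 if lab == SOLUBLE else 0 for lab in arr], dtype=int)
    return arr.astype(int)


def roc_auc(scores: Sequence[float] | np.ndarray, labels) -> float:
    """Area under the ROC curve for the rule "higher score => soluble".

    Computed in the rank (Mann-Whitney) form, which is exact under ties:
    AUC = P(score_sol > score_ins) + 0.5 * P(score_sol = score_ins) over all
    soluble-insoluble pairs.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)  # average ranks under ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_metrics(predictions, labels) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with soluble as the positive class.

    Sensitivity is the fraction of soluble sequences called soluble;
    specificity the fraction of insoluble sequences called insoluble.
    """
    pred = _as_binary(predictions)
    y = _as_binary(labels)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels differ in length")
    if y.size == 0:
        raise ValueError("empty input")
    accuracy = float((pred == y).mean())
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    sensitivity = float((pred[y == 1] == 1).mean()) if n_pos else float("nan")
    specificity = float((pred[y == 0] == 0).mean()) if n_neg else float("nan")
    return accuracy, sensitivity, specificity


def pearson_r(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Pearson product-moment correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input to Pearson correlation")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class FitnessResult:
    """One evaluated candidate card: the columns of a per-run summary row."""

    auc: float
    r: float
    fitness: float
    train_accuracy: float
    test_accuracy: float | None
    sensitivity: float
    specificity: float
    threshold: float

    def as_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
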