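"""Classification metrics: precision/recall/F-measure and ROC curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


def f_measure(p: float, r: float) -> float:
    """Harmonic mean of precision and recall, ``2pr/(p+r)`` (0 when both 0).

    Accepts either fractions in [0, 1] or percentages in [0, 100]; the
    result is returned on the same scale as the inputs.
    """
    percent = p > 1.0 or r > 1.0
    if percent:
        p, r = p / 100.0, r / 100.0
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError("precision and recall must be in [0,1] or [0,100]")
    f = 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0
    return f * 100.0 if percent else f


def precision_recall(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Precision and recall of the positive class from boolean arrays."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    tp = np.sum(y_true & y_pred)
    p = tp / y_pred.sum() if y_pred.sum() else 0.0
    r = tp / y_true.sum() if y_true.sum() else 0.0
    return float(p), float(r)


@dataclass
class Metrics:
    """Cross-validation summary: mean precision/recall/F plus ROC points."""

    precision: float
    recall: float
    f: float
    per_fold: list[tuple[float, float, float]] = field(default_factory=list)
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    auc: float | None = None

    @classmethod
    def from_folds(
        cls,
        fold_metrics: list[tuple[float, float, float]],
        y_true: np.ndarray | None = None,
        y_score: np.ndarray | None = None,
    ) -> "Metrics":
        arr = np.array(fold_metrics)
        m = cls(
            precision=float(arr[:, 0].mean()),
            recall=float(arr[:, 1].mean()),
            f=float(arr[:, 2].mean()),
            per_fold=fold_metrics,
        )
        if y_true is not None and y_score is not None and len(np.unique(y_true)) == 2:
            m.roc_fpr, m.roc_tpr, _ = roc_curve(y_true, y_score)
            m.auc = float(roc_auc_score(y_true, y_score))
        return m


def ranking_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve of a score ranking against binary truth."""
    return float(roc_auc_score(np.asarray(y_true, dtype=int), scores))
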