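"""Evaluation of the 10-class conductance classifier.

Per-class (one-vs-rest) recall, precision, F1, specificity and accuracy
from the confusion matrix; the overall score is the unweighted mean of
the ten per-class F1 values (macro-F1).  One-vs-rest ROC and
precision-recall curves with trapezoidal AUC complete the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cell_model import CONDUCTANCE_NAMES

__all__ = ["EvaluationReport", "confusion_matrix", "per_class_metrics",
           "macro_f1", "ovr_curves", "evaluate"]


def confusion_matrix(y_true, y_pred, n_classes: int = 10) -> np.ndarray:
    """Counts matrix: entry (i, j) = samples with true label i predicted j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"label outside 0-{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def per_class_metrics(cm: np.ndarray) -> dict[str, np.ndarray]:
    """One-vs-rest precision/recall/F1/specificity/accuracy per class.

    Undefined rates (empty class: TP+FN = 0, or no predicted positives)
    are reported as NaN rather than 0.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    n = cm.sum()
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = n - tp - fn - fp
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        # F1 is undefined only for an absent class (TP+FN = 0); a present
        # class with no true positives scores 0
        f1 = np.full(len(tp), np.nan)
        present = tp + fn > 0
        f1[present & (tp == 0)] = 0.0
        hit = present & (tp > 0)
        f1[hit] = (2 * precision[hit] * recall[hit]
                   / (precision[hit] + recall[hit]))
        specificity = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        accuracy = (tp + tn) / n if n > 0 else np.full(len(tp), np.nan)
    return {"precision": precision, "recall": recall, "f1": f1,
            "specificity": specificity, "accuracy": accuracy}


def macro_f1(per_class_f1) -> float:
    """Unweighted arithmetic mean of the per-class F1 scores."""
    f1 = np.asarray(per_class_f1, dtype=float)
    if np.isnan(f1).any():
        raise ValueError("missing per-class F1 value; cannot average")
    return float(np.mean(f1))


def ovr_curves(y_true, proba, n_classes: int = 10) -> dict[int, dict]:
    """One-vs-rest ROC and PR curves with trapezoidal AUC per class.

    Classes without positive samples are omitted (with a warning).
    """
    import warnings

    from sklearn.metrics import auc, precision_recall_curve, roc_curve

    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or proba.shape[0] != y_true.size:
        raise ValueError("probability matrix shape mismatch")
    row_sums = proba.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    out: dict[int, dict] = {}
    for c in range(n_classes):
        pos = y_true == c
        if not pos.any():
            warnings.warn(f"class {c} has no positive samples; curve omitted")
            continue
        scores = proba[:, c]
        fpr, tpr, _ = roc_curve(pos, scores)
        prec, rec, _ = precision_recall_curve(pos, scores)
        out[c] = {
            "fpr": fpr, "tpr": tpr, "roc_auc": float(auc(fpr, tpr)),
            "precision": prec, "recall": rec,
            "pr_auc": float(auc(rec[::-1], prec[::-1])),
        }
    return out


@dataclass
class EvaluationReport:
    """Confusion matrix, per-class rates, macro-F1 and OvR curves."""

    cm: np.ndarray
    per_class: dict[str, np.ndarray]
    macro_f1: float
    accuracy: float
    curves: dict[int, dict] = field(default_factory=dict)
    class_names: tuple[str, ...] = CONDUCTANCE_NAMES

    def to_dict(self) -> dict:
        d = {
            "confusion_matrix": self.cm.tolist(),
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "per_class": {k: [None if np.isnan(x) else float(x) for x in v]
                          for k, v in self.per_class.items()},
            "class_names": list(self.class_names),
        }
        if self.curves:
            d["auc"] = {str(c): {"roc": v["roc_auc"], "pr": v["pr_auc"]}
                        for c, v in self.curves.items()}
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(y_true, y_pred, proba=None, n_classes: int = 10,
             require_all_classes: bool = True) -> EvaluationReport:
    """Full evaluation from labels (and optionally probabilities)."""
    cm = confusion_matrix(y_true, y_pred, n_classes)
    pc = per_class_metrics(cm)
    if require_all_classes:
        f1_total = macro_f1(pc["f1"])
    else:
        present = ~np.isnan(pc["f1"])
        f1_total = float(np.mean(pc["f1"][present]))
    accuracy = float(np.trace(cm) / cm.sum()) if cm.sum() else float("nan")
    curves = ovr_curves(y_true, proba, n_classes) if proba is not None else {}
    return EvaluationReport(cm=cm, per_class=pc, macro_f1=f1_total,
                            accuracy=accuracy, curves=curves)
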