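"""Evaluation surface: per-class specificity/sensitivity, accuracy, F1,
ROC curves with Youden-optimal thresholds, and ranked confidence lists.

Specificity is TN/(TN+FP) and sensitivity TP/(TP+FN), computed one-vs-rest
for multi-class tasks.  Accuracy is reported as a percentage.  Two F1
conventions are emitted side by side — positive-class F1 (the natural choice
for the two-class tasks) and macro F1 (for the four-class task) — so reports
are unambiguous.  Classes absent from the test set get NaN rates, never 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import f1_score, roc_curve


@dataclass
class MetricsReport:
    classes: tuple
    confusion: np.ndarray               # rows = truth, cols = prediction
    specificity: np.ndarray             # per class, NaN if undefined
    sensitivity: np.ndarray
    accuracy: float                     # percent
    f1_positive: Optional[float]        # 2-class tasks: F1 of class index 1
    f1_macro: float
    roc: dict = field(default_factory=dict)        # class -> (fpr, tpr, thr)
    auc: dict = field(default_factory=dict)
    optimal_threshold: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "specificity": [None if np.isnan(v) else round(float(v), 6)
                            for v in self.specificity],
            "sensitivity": [None if np.isnan(v) else round(float(v), 6)
                            for v in self.sensitivity],
            "accuracy": round(float(self.accuracy), 4),
            "f1_positive": (None if self.f1_positive is None
                            else round(float(self.f1_positive), 6)),
            "f1_macro": round(float(self.f1_macro), 6),
            "auc": {c: round(float(v), 6) for c, v in self.auc.items()},
            "optimal_threshold": {c: round(float(v), 6)
                                  for c, v in self.optimal_threshold.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def summary(self) -> str:
        lines = [f"{'Class':<24}{'Specificity':>12}{'Sensitivity':>12}"]
        for i, c in enumerate(self.classes):
            sp = "   n/a" if np.isnan(self.specificity[i]) \
                else f"{self.specificity[i]:.2f}"
            se = "   n/a" if np.isnan(self.sensitivity[i]) \
                else f"{self.sensitivity[i]:.2f}"
            lines.append(f"{c:<24}{sp:>12}{se:>12}")
        lines.append(f"Accuracy: {self.accuracy:.2f}%")
        if self.f1_positive is not None:
            lines.append(f"F1 (positive class): {self.f1_positive:.2f}")
        lines.append(f"F1 (macro): {self.f1_macro:.2f}")
        for c, v in self.auc.items():
            lines.append(f"AUC [{c}]: {v:.3f}")
        return "\n".join(lines)


def specificity_sensitivity(confusion: np.ndarray):
    """One-vs-rest TN/(TN+FP) and TP/(TP+FN) per class; NaN when undefined."""
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
    return spec, sens


def roc_optimal_threshold(scores: Sequence[float], truth: Sequence[int]):
    """ROC over all cut-points and the Youden-J optimal threshold.

    J = sensitivity + specificity - 1 = TPR - FPR; ties break toward higher
    specificity (lower FPR, i.e. the more conservative threshold).
    Returns ``(threshold, fpr, tpr, thresholds, auc)``.
    """
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present to compute a ROC")
    fpr, tpr, thresholds = roc_curve(truth, np.asarray(scores, dtype=float))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    pick = best[np.argmin(fpr[best])]
    thr = thresholds[pick]
    if np.isinf(thr):
        thr = 1.0
    return float(thr), fpr, tpr, thresholds, float(sk_auc(fpr, tpr))


def auc_concordance(scores, truth) -> float:
    """Rank-statistic (Mann-Whitney) formulation of the AUC."""
    scores, truth = np.asarray(scores, float), np.asarray(truth)
    pos, neg = scores[truth == 1], scores[truth == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (pos.size * neg.size))


def compute_report(y_true, y_pred, proba: Optional[np.ndarray],
                   classes: tuple) -> MetricsReport:
    """Full evaluation report from truth, hard predictions and confidences.

    ``proba`` (n x n_classes softmax confidences) is optional; without it the
    ROC/AUC/threshold fields stay empty.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    labels = np.arange(len(classes))
    cm = sk_confusion(y_true, y_pred, labels=labels)
    spec, sens = specificity_sensitivity(cm)
    accuracy = 100.0 * cm.trace() / cm.sum()
    f1_pos = (float(f1_score(y_true, y_pred, labels=labels, pos_label=1,
                             average="binary", zero_division=0))
              if len(classes) == 2 else None)
    f1_mac = float(f1_score(y_true, y_pred, labels=labels, average="macro",
                            zero_division=0))
    roc, aucs, thresholds = {}, {}, {}
    if proba is not None:
        for i, cname in enumerate(classes):
            ovr = (y_true == i).astype(int)
            if len(np.unique(ovr)) < 2:
                continue
            thr, fpr, tpr, cuts, a = roc_optimal_threshold(proba[:, i], ovr)
            roc[cname] = (fpr, tpr, cuts)
            aucs[cname] = a
            thresholds[cname] = thr
    return MetricsReport(tuple(classes), cm, spec, sens, accuracy,
                         f1_pos, f1_mac, roc, aucs, thresholds)
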