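"""Decliner / stable / riser labelling and binary decliner detection.

An observation is a per-interval change; it is labelled from the relative BP
change (beyond -2%: decliner, beyond +2%: riser, otherwise stable) and the
relative PAT change serves as the predictor for detecting BP decliners —
the clinically relevant class, since a falling BP during dialysis is the
precursor of intradialytic hypotension.  PAT rises when BP falls, so the
positive prediction rule is ``rel_pat > threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = [
    "label_bp_class",
    "predict_decliner",
    "ConfusionMatrix",
    "confusion",
    "ROCCurve",
    "roc_auc",
]


def label_bp_class(rel_bp, threshold: float = 2.0):
    """Label relative BP changes (%) as decliner / stable / riser.

    Strict inequalities: exactly +/-threshold is stable.  Accepts scalars or
    arrays.
    """
    arr = np.asarray(rel_bp, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("relative changes must be finite")
    out = np.where(arr < -threshold, "decliner", np.where(arr > threshold, "riser", "stable"))
    return out.item() if np.isscalar(rel_bp) or arr.ndim == 0 else out


def predict_decliner(rel_pat, threshold: float = 2.0):
    """Predict decliner status from the relative PAT change (%).

    Positive iff ``rel_pat > threshold``: a PAT rise mirrors a BP fall.
    """
    arr = np.asarray(rel_pat, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("relative changes must be finite")
    out = arr > threshold
    return bool(out) if np.isscalar(rel_pat) or arr.ndim == 0 else out


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def f1(self) -> float:
        """Harmonic mean of precision and sensitivity (0 when tp = 0)."""
        p, s = self.precision, self.sensitivity
        if self.tp == 0:
            return 0.0
        return 2 * p * s / (p + s)


def confusion(labels, predictions) -> ConfusionMatrix:
    """Tally a binary confusion matrix (positive class = decliner)."""
    y = np.asarray(labels, dtype=bool)
    yhat = np.asarray(predictions, dtype=bool)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must have equal length")
    if y.size == 0:
        raise ValueError("confusion matrix undefined on empty input")
    return ConfusionMatrix(
        tp=int(np.sum(y & yhat)),
        fn=int(np.sum(y & ~yhat)),
        fp=int(np.sum(~y & yhat)),
        tn=int(np.sum(~y & ~yhat)),
    )


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and trapezoidal AUC, sweeping the unique score values.

    Scores are oriented so that higher values indicate the positive
    (decliner) class.  With only one class present the AUC is undefined and
    reported as NaN.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if y.all() or (~y).all():
        return ROCCurve(
            thresholds=np.array([]), fpr=np.array([]), tpr=np.array([]),
            auc=float("nan"),
        )
    fpr, tpr, thr = _roc_curve(y.astype(int), s)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))
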