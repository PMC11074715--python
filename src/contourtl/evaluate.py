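"""Confusion-matrix algebra, the seven binary-classification metrics, ROC-AUC,
and an exhaustive confusion-matrix reconstruction solver.

The positive class is "tumor present" (label 1).  Percentages are reported
to two decimals with round-half-up; rounding is applied only at reporting,
never in intermediate arithmetic.  Metrics whose denominator is zero are
reported as ``None`` (undefined) with a warning — silently substituting 0
would corrupt averages.

``solve_confusion`` inverts printed metric rows: given the class totals and
any subset of rounded metric values, it searches all integer (TP, TN) pairs
for the unique matrix that reproduces them — useful for recovering confusion
matrices that a report shows only as figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import AmbiguousSolution, NoSolution, ValidationError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "solve_confusion",
    "round2",
]


def round2(x: float) -> float:
    """Round-half-up to two decimals (the table-formatting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValidationError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The seven figures, percentages except ``roc_auc`` (a fraction in [0, 1]).

    Undefined entries (zero denominator) are ``None``.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    f1: Optional[float]
    roc_auc: Optional[float] = None

    def rounded(self) -> "MetricsReport":
        def r(v, nd=2):
            return None if v is None else round2(v)

        return MetricsReport(
            sensitivity=r(self.sensitivity),
            specificity=r(self.specificity),
            precision=r(self.precision),
            npv=r(self.npv),
            accuracy=r(self.accuracy),
            f1=r(self.f1),
            roc_auc=self.roc_auc,
        )

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
        }


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FP/TN/FN for binary labels (positive class = 1)."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.ndim != 1 or len(yt) == 0:
        raise ValidationError("y_true and y_pred must be equal-length 1-D, non-empty")
    if not (set(np.unique(yt)) | set(np.unique(yp))) <= {0, 1}:
        raise ValidationError("labels must be binary (0/1)")
    return ConfusionMatrix(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def _ratio(num: int, den: int, name: str) -> Optional[float]:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator)", stacklevel=3)
        return None
    return 100.0 * num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity, specificity, precision, NPV, accuracy and F1 (percent).

    F1 is the harmonic mean of precision and sensitivity, algebraically
    equal to ``100 * 2TP / (2TP + FP + FN)``.  ROC-AUC needs scores, not a
    matrix, and is left unset here (see :func:`roc_auc`).
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    prec = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    npv = _ratio(cm.tn, cm.tn + cm.fn, "npv")
    acc = _ratio(cm.tp + cm.tn, cm.total, "accuracy")
    if prec is None or sens is None or prec + sens == 0:
        if prec is not None and sens is not None:
            warnings.warn("f1 is undefined (precision + sensitivity = 0)", stacklevel=2)
        f1 = None
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return MetricsReport(
        sensitivity=sens, specificity=spec, precision=prec, npv=npv, accuracy=acc, f1=f1
    )


def roc_auc(y_true, scores) -> float:
    """P(random positive outscores random negative), ties counted half.

    Equivalent to the trapezoidal area under the ROC curve.
    """
    yt = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape or yt.ndim != 1:
        raise ValidationError("y_true and scores must be equal-length 1-D")
    if len(np.unique(yt)) < 2:
        raise ValidationError("roc_auc needs both classes present")
    return float(roc_auc_score(yt, s))


def solve_confusion(
    n_pos: int,
    n_neg: int,
    printed: dict[str, float],
) -> ConfusionMatrix:
    """Find the unique confusion matrix matching printed 2-decimal metrics.

    ``printed`` maps any subset of {sensitivity, specificity, precision, npv,
    accuracy, f1} (percent scale) to their published rounded values.  All
    (TP, TN) in [0, n_pos] x [0, n_neg] are enumerated; a candidate matches
    when every supplied metric, rounded half-up to 2 decimals, equals the
    printed value.  Raises if zero or more than one candidate survives.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("class totals must be >= 1")
    known = set(printed) - {"sensitivity", "specificity", "precision", "npv", "accuracy", "f1"}
    if known:
        raise ValidationError(f"unknown metric names: {sorted(known)}")

    # Vectorized enumeration of the whole (TP, TN) grid; half-up rounding with
    # a tiny nudge so exact .xx5 rationals round upward despite float storage.
    tp = np.arange(n_pos + 1, dtype=float)[:, None]
    tn = np.arange(n_neg + 1, dtype=float)[None, :]
    fp = n_neg - tn
    fn = n_pos - tp
    total = float(n_pos + n_neg)

    def r2(v):
        return np.floor(v * 100.0 + 0.5 + 1e-9) / 100.0

    with np.errstate(divide="ignore", invalid="ignore"):
        grid = {
            "sensitivity": 100.0 * tp / n_pos + 0.0 * tn,
            "specificity": 100.0 * tn / n_neg + 0.0 * tp,
            "precision": np.where(tp + fp > 0, 100.0 * tp / (tp + fp), np.nan),
            "npv": np.where(tn + fn > 0, 100.0 * tn / (tn + fn), np.nan),
            "accuracy": 100.0 * (tp + tn) / total,
            "f1": np.where(2 * tp + fp + fn > 0, 100.0 * 2 * tp / (2 * tp + fp + fn), np.nan),
        }
    ok = np.ones((n_pos + 1, n_neg + 1), dtype=bool)
    for name, value in printed.items():
        g = grid[name]
        ok &= ~np.isnan(g) & (r2(g) == round2(value))
    hits = np.argwhere(ok)
    if len(hits) == 0:
        raise NoSolution(f"no confusion matrix over ({n_pos}, {n_neg}) matches {printed}")
    if len(hits) > 1:
        raise AmbiguousSolution(
            f"{len(hits)} confusion matrices over ({n_pos}, {n_neg}) match {printed}"
        )
    tp_i, tn_i = (int(v) for v in hits[0])
    return ConfusionMatrix(tp=tp_i, fp=n_neg - tn_i, tn=tn_i, fn=n_pos - tp_i)
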