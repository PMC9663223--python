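"""Classification reliability: confusion counts, TPR/FPR, ROC curves, AUC.

TPR = TP/(TP+FN) and FPR = FP/(FP+TN), with the promotion (UPB) condition as
the positive class.  The ROC curve is the threshold sweep over the pooled
out-of-fold SVM decision scores; AUC is its trapezoidal area, which under the
diagonal tie-handling convention equals the Mann–Whitney pairwise-ranking
probability P(score⁺ > score⁻) + ½·P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve


class UndefinedRateError(ZeroDivisionError):
    """A rate whose denominator is zero (no positives / no negatives)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )


def tpr(c: ConfusionCounts) -> float:
    """True-positive rate TP/(TP+FN): fraction of UPB trials called UPB."""
    if c.tp + c.fn == 0:
        raise UndefinedRateError("TPR undefined: no positive samples")
    return c.tp / (c.tp + c.fn)


def fpr(c: ConfusionCounts) -> float:
    """False-positive rate FP/(FP+TN): fraction of non-UPB trials called UPB."""
    if c.fp + c.tn == 0:
        raise UndefinedRateError("FPR undefined: no negative samples")
    return c.fp / (c.fp + c.tn)


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep ROC from (0,0) to (1,1) with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve and AUC from decision scores; labels are 1 = UPB, 0 = non-UPB.

    Tied scores produce simultaneous diagonal steps, so the trapezoidal area
    is Mann–Whitney-consistent.  AUC > 0.5 means the ranking separates the
    classes better than chance; 1.0 is a perfect ranking.
    """
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr_pts, tpr_pts, thr = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    area = float(np.trapezoid(tpr_pts, fpr_pts))
    return ROCCurve(fpr=fpr_pts, tpr=tpr_pts, thresholds=thr, auc=area)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Half-up decimal rounding (report display convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def auc_report(per_subject_auc: dict[int, float] | list[float]) -> pd.DataFrame:
    """Per-subject AUC table plus summary rows (mean, sample SD, SEM, min, max).

    Values are reported both at full precision and half-up rounded to two
    decimals for display.
    """
    if isinstance(per_subject_auc, dict):
        items = sorted(per_subject_auc.items())
    else:
        items = list(enumerate(per_subject_auc, start=1))
    if not items:
        raise ValueError("no AUC values")
    values = np.array([v for _, v in items], dtype=float)
    rows = [{"subject": str(s), "auc": float(v)} for s, v in items]
    n = values.size
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    summary = {
        "Average": float(np.mean(values)),
        "SD": sd,
        "SEM": sd / np.sqrt(n),
        "Min": float(np.min(values)),
        "Max": float(np.max(values)),
    }
    rows += [{"subject": k, "auc": v} for k, v in summary.items()]
    df = pd.DataFrame(rows)
    df["auc_display"] = [round_half_up(v, 2) for v in df["auc"]]
    return df
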