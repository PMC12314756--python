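"""Imbalance-aware evaluation metrics.

High suicidal ideation (class 1) is the positive class.  Because positives
are ~8x rarer than negatives, accuracy is uninformative; the pipeline reports
precision/recall per class, per-class F1 and their macro average, the G-mean
(geometric mean of the two recalls, zero whenever a class is missed
entirely), and the false positive rate.

Zero-denominator rule: any precision or recall whose denominator is zero is
defined as 0, and an F1 whose precision + recall is zero is 0.  This keeps
the all-negative predictor (a real failure mode under heavy imbalance)
well-defined with recall_1 = G-mean = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


@dataclass(frozen=True)
class Confusion:
    """Binary confusion counts; class 1 (high ideation) is positive."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class EvalReport:
    """The metric panel, all proportions in [0, 1]."""

    precision_0: float
    recall_0: float
    precision_1: float
    recall_1: float
    F1_0: float
    F1_1: float
    macro_F1: float
    G_mean: float
    FPR: float

    METRICS = (
        "precision_0", "recall_0", "precision_1", "recall_1",
        "F1_0", "F1_1", "macro_F1", "G_mean", "FPR",
    )

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in self.METRICS}

    def as_percent(self) -> dict[str, float]:
        """Percentages rounded half-up to 2 decimals, as printed in tables."""
        return {m: round_percent(getattr(self, m)) for m in self.METRICS}


def round_percent(proportion: float, ndigits: int = 2) -> float:
    """Half-up rounding of a proportion on the percentage scale."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(proportion * 100)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(y_true, y_pred) -> Confusion:
    """Exact confusion counts for binary label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    for v in (y_true, y_pred):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be binary")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return Confusion(TP=tp, TN=tn, FP=fp, FN=fn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def _f1(p: float, r: float) -> float:
    return _safe_div(2 * p * r, p + r)


def report(c: Confusion) -> EvalReport:
    """Compute the full metric panel from confusion counts."""
    precision_0 = _safe_div(c.TN, c.TN + c.FN)
    recall_0 = _safe_div(c.TN, c.TN + c.FP)
    precision_1 = _safe_div(c.TP, c.TP + c.FP)
    recall_1 = _safe_div(c.TP, c.TP + c.FN)
    f1_0 = _f1(precision_0, recall_0)
    f1_1 = _f1(precision_1, recall_1)
    return EvalReport(
        precision_0=precision_0,
        recall_0=recall_0,
        precision_1=precision_1,
        recall_1=recall_1,
        F1_0=f1_0,
        F1_1=f1_1,
        macro_F1=0.5 * (f1_0 + f1_1),
        G_mean=float(np.sqrt(recall_1 * recall_0)),
        FPR=_safe_div(c.FP, c.FP + c.TN),
    )


def evaluate(y_true, y_pred) -> EvalReport:
    """Convenience: confusion + report in one call."""
    return report(confusion(y_true, y_pred))


def reconstruct_confusion(
    recall_1: float, fpr: float, n_pos: int, n_neg: int
) -> Confusion:
    """Recover integer confusion counts from printed recall_1 and FPR.

    Published tables report rates at 2 decimals; with known class totals the
    underlying integer counts are TP = round(recall_1 * n_pos) and
    FP = round(fpr * n_neg).  Used to audit printed metric panels.
    """
    for name, v in (("recall_1", recall_1), ("fpr", fpr)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a proportion in [0,1]")
    tp = int(round(recall_1 * n_pos))
    fp = int(round(fpr * n_neg))
    return Confusion(TP=tp, FN=n_pos - tp, FP=fp, TN=n_neg - fp)
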