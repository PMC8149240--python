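"""Confusion-count algebra and the five clinical evaluation metrics.

Accuracy, sensitivity, specificity and precision are reported as
percentages rounded half-up to two decimals; the F-score is a ratio in
[0, 1], also to two decimals.  A zero denominator yields ``None`` (an
explicit undefined marker), never 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Percentages to two decimals; ``None`` marks an undefined metric."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f_score: float | None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f_score": self.f_score,
        }


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    q = (Decimal(num) / Decimal(den) * 100).quantize(Decimal("0.01"),
                                                     rounding=ROUND_HALF_UP)
    return float(q)


def _ratio(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return float((Decimal(num) / Decimal(den)).quantize(Decimal("0.01"),
                                                        rounding=ROUND_HALF_UP))


def confusion(preds, labels) -> ConfusionCounts:
    """Tabulate the 2x2 confusion matrix with class 1 positive."""
    preds = np.asarray(preds, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if preds.shape != labels.shape:
        raise ValueError("prediction and label vectors differ in length")
    if not (np.isin(preds, [0, 1]).all() and np.isin(labels, [0, 1]).all()):
        raise ValueError("binary 0/1 vectors required")
    return ConfusionCounts(
        TP=int(((preds == 1) & (labels == 1)).sum()),
        TN=int(((preds == 0) & (labels == 0)).sum()),
        FP=int(((preds == 1) & (labels == 0)).sum()),
        FN=int(((preds == 0) & (labels == 1)).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision (percent) and F-score.

    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100
    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100
    precision   = TP / (TP + FP) * 100
    F-score     = 2 TP / (2 TP + FP + FN)
    """
    if c.total == 0:
        raise ValueError("no evaluated instances")
    return MetricsReport(
        accuracy=_pct(c.TP + c.TN, c.total),
        sensitivity=_pct(c.TP, c.TP + c.FN),
        specificity=_pct(c.TN, c.TN + c.FP),
        precision=_pct(c.TP, c.TP + c.FP),
        f_score=_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
    )
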