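"""Screening metrics: confusion counts, sensitivity, specificity, accuracy.

Positive means ischemia.  Metrics are percentages kept at full precision
internally; display rounding is half-up to one decimal.  A metric whose
denominator is empty is undefined and reported as ``None``, never as a
number.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 screening outcome counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def confusion(truth, predicted) -> ConfusionCounts:
    """Count TP/TN/FP/FN from binary label sequences (1 = ischemia)."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    if not set(np.unique(np.concatenate([truth, predicted])).tolist()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((truth == 1) & (predicted == 1))),
        tn=int(np.sum((truth == 0) & (predicted == 0))),
        fp=int(np.sum((truth == 0) & (predicted == 1))),
        fn=int(np.sum((truth == 1) & (predicted == 0))),
    )


def sensitivity(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN) as a percent; None when no positives exist."""
    denom = c.tp + c.fn
    return None if denom == 0 else 100.0 * c.tp / denom


def specificity(c: ConfusionCounts) -> float | None:
    """TN / (TN + FP) as a percent; None when no negatives exist."""
    denom = c.tn + c.fp
    return None if denom == 0 else 100.0 * c.tn / denom


def accuracy(c: ConfusionCounts) -> float | None:
    """(TP + TN) / total as a percent; None on empty input."""
    return None if c.total == 0 else 100.0 * (c.tp + c.tn) / c.total


def balanced_accuracy(c: ConfusionCounts) -> float | None:
    """Mean of sensitivity and specificity (percent)."""
    sen, spe = sensitivity(c), specificity(c)
    if sen is None or spe is None:
        return None
    return (sen + spe) / 2.0


def round_display(value: float | None, decimals: int = 1) -> float | None:
    """Half-up rounding for report display (84.25 -> 84.3)."""
    if value is None:
        return None
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def metrics_report(c: ConfusionCounts) -> dict:
    """All metrics for one confusion table, display-rounded to one decimal."""
    return {
        "TP": c.tp, "TN": c.tn, "FP": c.fp, "FN": c.fn, "n": c.total,
        "SEN": round_display(sensitivity(c)),
        "SPE": round_display(specificity(c)),
        "ACC": round_display(accuracy(c)),
    }


def evaluate_by_group(truth, predicted, groups=None) -> pd.DataFrame:
    """Per-group confusion metrics plus a total row.

    ``groups`` is an optional per-sample key (e.g. source database); without
    it only the total row is produced.
    """
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    rows = []
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            sel = groups == g
            rows.append({"group": str(g), **metrics_report(confusion(truth[sel], predicted[sel]))})
    rows.append({"group": "total", **metrics_report(confusion(truth, predicted))})
    return pd.DataFrame(rows)
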