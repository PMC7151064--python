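"""Confusion counts and prevalence-based validation metrics.

From TP/TN/FP/FN (positive class = condition/depressive) the report derives
sensitivity TP/(TP+FN), specificity TN/(TN+FP), prevalence (TP+FN)/total,
and the prevalence forms of the predictive values:

    PPV = sens*prev / (sens*prev + (1-spec)*(1-prev))
    NPV = spec*(1-prev) / ((1-sens)*prev + spec*(1-prev))

which, with prevalence taken from the counts, coincide algebraically with the
count forms TP/(TP+FP) and TN/(TN+FN).  Accuracy is (TP+TN)/total.  Percent
formatting rounds half-up to 2 decimals.  A metric with a zero denominator is
reported as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """The four outcome cells of a binary classification."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def format_percent(x: float) -> str:
    """Half-up 2-decimal percent string, e.g. 0.99716... -> '99.72%'."""
    if math.isnan(x):
        return "NA"
    q = Decimal(repr(x * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return f"{q}%"


@dataclass(frozen=True)
class ValidationReport:
    """Five derived rates plus prevalence, all as proportions in [0, 1]."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    prevalence: float

    def as_percent_strings(self) -> dict[str, str]:
        return {
            "sensitivity": format_percent(self.sensitivity),
            "specificity": format_percent(self.specificity),
            "ppv": format_percent(self.ppv),
            "npv": format_percent(self.npv),
            "accuracy": format_percent(self.accuracy),
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally the four outcome cells; positive class is 1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    if y_true.size == 0:
        raise ValueError("empty label lists")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(counts: ConfusionCounts) -> ValidationReport:
    """Derive the validation report from confusion counts."""
    total = counts.total
    if total == 0:
        raise ValueError("empty confusion table")
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    prev = counts.tp / total + counts.fn / total
    ppv = _ratio(sens * prev, sens * prev + (1 - spec) * (1 - prev))
    npv = _ratio(spec * (1 - prev), (1 - sens) * prev + spec * (1 - prev))
    acc = (counts.tp + counts.tn) / total
    return ValidationReport(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        accuracy=acc, prevalence=prev,
    )
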