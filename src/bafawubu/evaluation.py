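"""Confusion-matrix evaluation with per-class accuracy reporting.

"Accuracy" per class is the true-class recall: correctly classified windows
of a class divided by all windows of that class (diagonal over row sum).
Percentages are rounded half-up to one decimal, the precision reports in
this area are printed at.
"""

from __future__ import annotations

import dataclasses
import decimal
import json

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from bafawubu.movements import CLASS_ORDER, as_code

CLASS_CODES = tuple(c.value for c in CLASS_ORDER)


def _round_half_up(value: float, decimals: int = 1) -> float:
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(value))).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP))


@dataclasses.dataclass
class ConfusionMatrix:
    """7x7 counts; rows = true class, columns = predicted class, in the
    canonical order (WOF, LF, RBB, PB, PPS, ELS, SKR)."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_CODES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclasses.dataclass(frozen=True)
class ClassMetrics:
    """One report row: correctly / incorrectly classified windows of a true
    class and the resulting percentage (None when the class never occurs —
    undefined, not zero)."""

    movement: str
    true_count: int
    false_count: int

    @property
    def accuracy_pct(self) -> float | None:
        denom = self.true_count + self.false_count
        if denom == 0:
            return None
        return _round_half_up(100.0 * self.true_count / denom)


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count (true, predicted) pairs into the canonical 7x7 matrix."""
    true_codes = [as_code(label) for label in true_labels]
    pred_codes = [as_code(label) for label in predicted_labels]
    if len(true_codes) != len(pred_codes):
        raise ValueError("label sequences differ in length")
    for code in (*true_codes, *pred_codes):
        if code not in CLASS_CODES:
            raise ValueError(f"label {code!r} is not a movement class")
    counts = _sk_confusion(true_codes, pred_codes, labels=list(CLASS_CODES))
    return ConfusionMatrix(counts=counts)


def per_class_accuracy(cm: ConfusionMatrix) -> list[ClassMetrics]:
    """Per-class recall rows: true = diagonal, false = row sum - diagonal."""
    rows = []
    for i, code in enumerate(cm.classes):
        true_count = int(cm.counts[i, i])
        false_count = int(cm.counts[i].sum() - cm.counts[i, i])
        rows.append(ClassMetrics(code, true_count, false_count))
    return rows


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 x trace / total, rounded half-up to one decimal."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return _round_half_up(100.0 * np.trace(cm.counts) / cm.total)


def report(cm: ConfusionMatrix) -> dict:
    """JSON-serializable evaluation report: per-class rows + matrix."""
    return {
        "classes": list(cm.classes),
        "matrix": cm.counts.tolist(),
        "per_class": [
            {"class": row.movement, "true_count": row.true_count,
             "false_count": row.false_count, "accuracy_pct": row.accuracy_pct}
            for row in per_class_accuracy(cm)
        ],
        "overall_accuracy_pct": overall_accuracy(cm),
    }


def report_to_csv(cm: ConfusionMatrix, path) -> None:
    """Export the per-class table (Motion, True Count, False Count,
    Accuracy) as CSV."""
    rows = per_class_accuracy(cm)
    frame = pd.DataFrame({
        "Motion": [r.movement for r in rows],
        "True Count": [r.true_count for r in rows],
        "False Count": [r.false_count for r in rows],
        "Accuracy": [f"{r.accuracy_pct}%" if r.accuracy_pct is not None
                     else "undefined" for r in rows],
    })
    frame.to_csv(path, index=False)


def report_to_json(cm: ConfusionMatrix, path) -> None:
    with open(path, "w") as fh:
        json.dump(report(cm), fh, indent=2)
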