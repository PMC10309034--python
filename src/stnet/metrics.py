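"""Confusion-count evaluation metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "compute_metrics", "EvalReport"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return ConfusionCounts(
            tp=int((y_true & y_pred).sum()),
            tn=int((~y_true & ~y_pred).sum()),
            fp=int((~y_true & y_pred).sum()),
            fn=int((y_true & ~y_pred).sum()),
        )


@dataclass(frozen=True)
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def compute_metrics(counts: ConfusionCounts) -> EvalReport:
    """Accuracy, precision, recall and F1 from confusion counts.

    Degenerate denominators (no predicted positives, no true positives, or
    precision + recall = 0) yield 0 for the affected metric.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics over zero samples")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc = (tp + tn) / counts.total
    pre = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    rec = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * pre * rec / (pre + rec) if (pre + rec) > 0 else 0.0
    return EvalReport(acc, pre, rec, f1)
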