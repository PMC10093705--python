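"""Confusion counts and the five screening metrics.

With the abnormal (malignant) class as positive:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)            (recall)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * recall / (precision + recall)

A ratio with a zero denominator is reported as 0.0 and the affected
metric names are listed in ``MetricReport.undefined`` rather than
propagating NaN into reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, ShapeError

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    undefined: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
        }


def confusion(true_labels, predicted_labels, positive_class) -> ConfusionCounts:
    """Count TP/TN/FP/FN treating ``positive_class`` as positive."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ShapeError(f"{y.shape[0]} true labels vs {p.shape[0]} predictions")
    pos_t = y == positive_class
    pos_p = p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Compute the five metrics from a confusion quadruple."""
    if counts.total == 0:
        raise InvalidInputError("cannot compute metrics on zero samples")
    undefined: list[str] = []
    acc = (counts.tp + counts.tn) / counts.total
    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity", undefined)
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity", undefined)
    prec = _ratio(counts.tp, counts.tp + counts.fp, "precision", undefined)
    if "precision" in undefined or "sensitivity" in undefined or prec + sens == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return MetricReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        undefined=tuple(dict.fromkeys(undefined)),
    )
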