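"""Confusion-matrix metrics, ROC/AUC, and cross-validation fold aggregation.

All derived metrics are percentages in [0, 100]. They are computed in full
precision and rounded half-up to two decimals only at serialization time,
matching the usual benchmark-table format. The accuracy has two variants:
the ``standard`` overall correctness (TP+TN)/total (default) and a
``literal`` TP/(TP+FP) variant kept for transparency — some published
write-ups print the precision formula under the accuracy heading. The default
error rate is 100 - accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "accuracy_pct",
    "precision_pct",
    "recall_pct",
    "f_measure_pct",
    "error_rate_pct",
    "roc_points",
    "RocCurve",
    "aggregate_folds",
    "round2",
    "reports_to_tsv",
]


def round2(x: float) -> float:
    """Round half-up to two decimals (NaN passes through)."""
    if isinstance(x, float) and np.isnan(x):
        return x
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN tallies for a chosen positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    labels: np.ndarray, predictions: np.ndarray, positive_class: int = 1
) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape or labels.size < 1:
        raise ValidationError("labels and predictions must have equal non-zero length")
    pos = labels == positive_class
    pred_pos = predictions == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def accuracy_pct(c: ConfusionCounts, variant: str = "standard") -> float:
    if variant == "standard":
        if c.total == 0:
            raise UndefinedMetricError("no samples")
        return 100.0 * (c.tp + c.tn) / c.total
    if variant == "literal":
        if c.tp + c.fp == 0:
            raise UndefinedMetricError("no predicted positives")
        return 100.0 * c.tp / (c.tp + c.fp)
    raise ValidationError(f"unknown accuracy variant {variant!r}")


def precision_pct(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no predicted positives")
    return 100.0 * c.tp / (c.tp + c.fp)


def recall_pct(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no actual positives")
    return 100.0 * c.tp / (c.tp + c.fn)


def f_measure_pct(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R) of two percentages; 0 when both are 0."""
    if precision < 0 or recall < 0:
        raise ValidationError("precision/recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def error_rate_pct(report_accuracy: float) -> float:
    """Complement of accuracy: 100 - accuracy."""
    if not (0.0 <= report_accuracy <= 100.0):
        raise ValidationError("accuracy must lie in [0, 100]")
    return 100.0 - report_accuracy


@dataclass
class MetricsReport:
    """The five percentage metrics of a single evaluation."""

    accuracy: float
    precision: float
    recall: float
    f_measure: float
    error_rate: float

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "MetricsReport":
        acc = accuracy_pct(c)
        try:
            prec = precision_pct(c)
        except UndefinedMetricError:
            prec = float("nan")
        try:
            rec = recall_pct(c)
        except UndefinedMetricError:
            rec = float("nan")
        f = f_measure_pct(prec, rec) if not (np.isnan(prec) or np.isnan(rec)) else float("nan")
        return cls(acc, prec, rec, f, error_rate_pct(acc))

    @classmethod
    def from_predictions(
        cls, labels: np.ndarray, predictions: np.ndarray, positive_class: int = 1
    ) -> "MetricsReport":
        return cls.from_counts(confusion(labels, predictions, positive_class))

    def rounded(self) -> dict[str, float]:
        return {f.name: round2(getattr(self, f.name)) for f in fields(self)}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.rounded(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def aggregate_folds(reports: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of each metric across folds."""
    if not reports:
        raise ValidationError("aggregate_folds needs at least one report")
    return MetricsReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f_measure=float(np.mean([r.f_measure for r in reports])),
        error_rate=float(np.mean([r.error_rate for r in reports])),
    )


def reports_to_tsv(reports: dict[str, MetricsReport], path: str | Path | None = None) -> str:
    """Serialize reports as a metrics-as-rows table (two-decimal cells)."""
    names = list(reports)
    lines = ["Metrics\t" + "\t".join(names)]
    for metric in ("accuracy", "precision", "recall", "f_measure", "error_rate"):
        cells = [f"{round2(getattr(reports[n], metric)):.2f}" for n in names]
        lines.append(metric + "\t" + "\t".join(cells))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_tsv(self, path: str | Path) -> None:
        lines = ["fpr\ttpr\tthreshold"]
        for f, t, th in zip(self.fpr, self.tpr, self.thresholds):
            lines.append(f"{f!r}\t{t!r}\t{th!r}")
        Path(path).write_text("\n".join(lines) + "\n")


def roc_points(
    scores: np.ndarray, labels: np.ndarray, positive_class: int = 1
) -> RocCurve:
    """ROC curve over descending unique score thresholds, plus trapezoidal AUC.

    ``scores`` are the classifier's scores for the positive class; a sample is
    called positive when its score is >= the threshold. A sentinel threshold
    above the maximum score anchors the curve at (0, 0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    pos = labels == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, th in enumerate(thresholds):
        called = scores >= th
        tpr[i] = np.sum(called & pos) / n_pos
        fpr[i] = np.sum(called & ~pos) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)
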