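"""Confusion matrices and the weighted one-vs-all metric suite.

Matrix convention: **rows = predicted class, columns = real class**, in
the fixed order (negative, neutral, positive).  All formulas below are
written against this orientation; note it is the transpose of the more
common rows-true layout.

For each class c the 3x3 matrix collapses to a 2x2 one-vs-all table
(TP, FP, FN, TN), from which per-class accuracy (TP+TN)/N, precision
TP/(TP+FP), recall TP/(TP+FN) and F1 are computed.  The weighted suite
sums each per-class metric weighted by real-class support / N.  Two
algebraic identities worth knowing:

* support-weighted recall == trace/total == plain accuracy;
* per-class one-vs-all accuracy is invariant under transposition (FP and
  FN swap), so the weighted accuracy is transpose-invariant whenever the
  support weights are pinned to the dataset's class sizes rather than
  recomputed from the transposed matrix.

Percents are kept as exact floats internally; display rounding is
half-up to two decimals (a truncation formatter is also provided, since
published tables sometimes truncate instead of rounding).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .labels import CLASSES, validate_label
from .synthetic_data import Testimony


class UndefinedMetricError(ValueError):
    """A metric was requested on an empty confusion matrix."""


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 integer counts; ``counts[p][r]`` = predicted class p, real class r."""

    counts: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3):
            raise ValueError(f"confusion matrix must be 3x3, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @classmethod
    def from_array(cls, arr) -> "ConfusionMatrix3":
        a = np.asarray(arr, dtype=int)
        return cls(tuple(tuple(int(x) for x in row) for row in a))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def total(self) -> int:
        return int(self.array.sum())

    @property
    def supports(self) -> np.ndarray:
        """Real-class sizes: the column sums."""
        return self.array.sum(axis=0)

    def transpose(self) -> "ConfusionMatrix3":
        return ConfusionMatrix3.from_array(self.array.T)


def confusion_matrix(pairs: Sequence[tuple[str, str]]) -> ConfusionMatrix3:
    """Tally (predicted, real) label pairs into a rows-predicted matrix."""
    for p, r in pairs:
        validate_label(p)
        validate_label(r)
    if not pairs:
        return ConfusionMatrix3.from_array(np.zeros((3, 3), dtype=int))
    predicted = [p for p, _ in pairs]
    real = [r for _, r in pairs]
    # sklearn tallies rows=true; transpose into the rows-predicted convention
    arr = _sk_confusion(real, predicted, labels=list(CLASSES)).T
    return ConfusionMatrix3.from_array(arr)


def accuracy(cm: ConfusionMatrix3) -> float:
    """Plain 3-class accuracy as a percent: 100 * trace / total."""
    if cm.total == 0:
        raise UndefinedMetricError("accuracy is undefined on an empty confusion matrix")
    return 100.0 * float(np.trace(cm.array)) / cm.total


@dataclass(frozen=True)
class ClassMetrics:
    label: str
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float  # percents
    recall: float
    f1: float
    accuracy: float
    support: int


@dataclass(frozen=True)
class MetricReport:
    """Accuracy plus the support-weighted one-vs-all metric suite (percents)."""

    accuracy: float
    weighted_accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    per_class: tuple[ClassMetrics, ...]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "weighted_accuracy": self.weighted_accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "per_class": {
                m.label: {
                    "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
                    "precision": m.precision, "recall": m.recall,
                    "f1": m.f1, "accuracy": m.accuracy, "support": m.support,
                }
                for m in self.per_class
            },
        }


def weighted_one_vs_all(cm: ConfusionMatrix3, supports: Sequence[int] | None = None) -> MetricReport:
    """Collapse the matrix per class into 2x2 tables and weight by support.

    ``supports`` defaults to the matrix's real-class column sums; pass the
    dataset's class sizes explicitly when evaluating a transformed (e.g.
    transposed) matrix so the weights stay a property of the data.
    A class with no predicted items gets precision 0 with a warning.
    """
    n = cm.total
    if n == 0:
        raise UndefinedMetricError("metrics are undefined on an empty confusion matrix")
    arr = cm.array
    w = np.asarray(supports if supports is not None else cm.supports, dtype=float)
    if w.shape != (3,) or w.sum() <= 0:
        raise ValueError("supports must be three non-negative counts with positive sum")
    per_class: list[ClassMetrics] = []
    for k, label in enumerate(CLASSES):
        tp = int(arr[k, k])
        fp = int(arr[k, :].sum() - tp)  # predicted k, real other
        fn = int(arr[:, k].sum() - tp)  # real k, predicted other
        tn = n - tp - fp - fn
        if tp + fp == 0:
            warnings.warn(
                f"no items predicted as {label!r}; precision for this class set to 0",
                UserWarning,
                stacklevel=2,
            )
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class.append(
            ClassMetrics(
                label=label, tp=tp, fp=fp, fn=fn, tn=tn,
                precision=100.0 * prec, recall=100.0 * rec,
                f1=100.0 * f1, accuracy=100.0 * (tp + tn) / n,
                support=int(arr[:, k].sum()),
            )
        )
    weights = w / w.sum()
    agg = lambda attr: float(sum(wk * getattr(m, attr) for wk, m in zip(weights, per_class)))
    return MetricReport(
        accuracy=accuracy(cm),
        weighted_accuracy=agg("accuracy"),
        weighted_precision=agg("precision"),
        weighted_recall=agg("recall"),
        weighted_f1=agg("f1"),
        per_class=tuple(per_class),
    )


@dataclass(frozen=True)
class Misclassification:
    id: str
    text: str
    gold: str
    predicted: str


@dataclass(frozen=True)
class MisclassificationReport:
    entries: tuple[Misclassification, ...]

    def by_cell(self) -> dict[tuple[str, str], list[Misclassification]]:
        """Group entries by (gold, predicted) pair."""
        cells: dict[tuple[str, str], list[Misclassification]] = {}
        for e in self.entries:
            cells.setdefault((e.gold, e.predicted), []).append(e)
        return cells

    def __len__(self) -> int:
        return len(self.entries)


def misclassification_report(
    testimonies: Sequence[Testimony], predictions: Sequence[str]
) -> MisclassificationReport:
    """List every testimony whose prediction disagrees with its gold label."""
    if len(testimonies) != len(predictions):
        raise ValueError(
            f"got {len(predictions)} predictions for {len(testimonies)} testimonies"
        )
    entries = []
    for t, p in zip(testimonies, predictions):
        validate_label(p)
        if t.gold is None:
            raise ValueError(f"testimony {t.id!r} has no gold label")
        if t.gold != p:
            entries.append(Misclassification(id=t.id, text=t.text, gold=t.gold, predicted=p))
    return MisclassificationReport(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Display helpers and serialisation


def round_percent(x: float, decimals: int = 2) -> float:
    """Round half up (the convention used for displayed percents)."""
    q = 10.0**decimals
    return float(np.floor(x * q + 0.5) / q)


def truncate_percent(x: float, decimals: int = 2) -> float:
    """Truncate toward zero (some published tables truncate, not round)."""
    q = 10.0**decimals
    return float(np.trunc(x * q) / q)


def matrix_to_tsv(cm: ConfusionMatrix3, path: str | Path) -> None:
    lines = ["predicted\\real\t" + "\t".join(CLASSES)]
    for label, row in zip(CLASSES, cm.counts):
        lines.append(label + "\t" + "\t".join(str(x) for x in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def report_to_json(report: MetricReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2), encoding="utf-8")
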