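"""Confusion-matrix construction and per-class / macro classification metrics.

Rows of the matrix are the actual class, columns the predicted class.  Metrics
follow the one-vs-rest decomposition per class c (TP the diagonal cell, FP the
rest of column c, FN the rest of row c):

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Overall accuracy is trace/total (the multiclass generalization of the binary
(TP+TN)/n form), and the summary precision/recall/F1 are macro averages —
unweighted means of the per-class values.  All metrics are reported in percent.
0/0 conventions: a class never predicted has precision 0 (with a warning);
F1 is 0 when precision + recall is 0.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "MetricReport", "confusion", "class_metrics",
           "macro_metrics", "report", "parse_report"]

_CLASSES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 counts; rows = actual class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...] = _CLASSES

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(self.classes),) * 2 or (c < 0).any():
            raise ValueError("counts must be a nonnegative square matrix")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


@dataclass(frozen=True)
class MetricReport:
    """Per-class and macro metrics, all in percent."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    classes: tuple[str, ...] = _CLASSES


def confusion(y_true, y_pred, classes=_CLASSES) -> ConfusionMatrix:
    """Tally actual-vs-predicted label pairs into a confusion matrix."""
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    lut = {c: k for k, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in lut or p not in lut:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        counts[lut[t], lut[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def class_metrics(cm: ConfusionMatrix):
    """One-vs-rest precision, recall and F1 per class, in percent."""
    counts = np.asarray(cm.counts, dtype=float)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    precision = np.zeros_like(tp)
    recall = np.zeros_like(tp)
    f1 = np.zeros_like(tp)
    for c in range(len(tp)):
        if tp[c] + fp[c] == 0:
            warnings.warn(f"class {cm.classes[c]} never predicted; precision set to 0",
                          stacklevel=2)
            precision[c] = 0.0
        else:
            precision[c] = tp[c] / (tp[c] + fp[c])
        recall[c] = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] > 0 else 0.0
        s = precision[c] + recall[c]
        f1[c] = 2 * precision[c] * recall[c] / s if s > 0 else 0.0
    return 100 * precision, 100 * recall, 100 * f1


def macro_metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(accuracy, macro precision, macro recall, macro F1), in percent."""
    counts = np.asarray(cm.counts, dtype=float)
    accuracy = 100.0 * np.trace(counts) / counts.sum()
    precision, recall, f1 = class_metrics(cm)
    return (float(accuracy), float(precision.mean()), float(recall.mean()),
            float(f1.mean()))


def report(cm: ConfusionMatrix, metadata: dict | None = None) -> MetricReport:
    """Full metric report for one confusion matrix."""
    precision, recall, f1 = class_metrics(cm)
    accuracy, mp, mr, mf1 = macro_metrics(cm)
    rep = MetricReport(accuracy=accuracy, macro_precision=mp, macro_recall=mr,
                       macro_f1=mf1, precision=tuple(precision),
                       recall=tuple(recall), f1=tuple(f1), classes=cm.classes)
    return rep


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding: half away from zero at ``ndigits`` decimals."""
    factor = 10.0**ndigits
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


def to_json(rep: MetricReport, metadata: dict | None = None) -> str:
    payload = asdict(rep)
    if metadata:
        payload["metadata"] = metadata
    return json.dumps(payload, indent=2)


def parse_report(text: str) -> MetricReport:
    payload = json.loads(text)
    payload.pop("metadata", None)
    for key in ("precision", "recall", "f1", "classes"):
        payload[key] = tuple(payload[key])
    return MetricReport(**payload)


def f1_curve_csv(rep: MetricReport) -> str:
    """Per-class F1 values as CSV (the data behind an F1-versus-class curve)."""
    df = pd.DataFrame({"class": rep.classes, "f1_percent": rep.f1})
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()


def confusion_csv(cm: ConfusionMatrix) -> str:
    """Confusion matrix as CSV with labelled header row/column."""
    df = pd.DataFrame(np.asarray(cm.counts), index=list(cm.classes),
                      columns=list(cm.classes))
    buf = io.StringIO()
    df.to_csv(buf, index_label="actual\\predicted")
    return buf.getvalue()
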