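"""Confusion-matrix construction and the five evaluation quantities.

Per class c (one-vs-rest: samples of class c are positive, the other two
classes negative):

* precision  P  = TP / (TP + FP)
* recall     R  = TP / (TP + FN)
* F1         F1 = 2 P R / (P + R)
* error      E  = 1 - TP / (TP + FN) = 1 - R

Overall accuracy is micro accuracy, total correct / total evaluated. All
quantities are reported as percentages rounded half-up to 2 decimals, the
convention used in published origin-classification tables. A class with no
predicted positives has undefined precision (reported as None, with F1
omitted) rather than a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from ovotrace.core import ORIGIN_NAMES, VALID_LABELS
from ovotrace.errors import ValidationError

N_CLASSES = 3


def round2(value: float) -> float:
    """Round half-up to 2 decimals (matches printed-table convention)."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (N_CLASSES, N_CLASSES) or (c < 0).any():
            raise ValidationError("counts must be a non-negative 3x3 matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self, label: int) -> int:
        return int(self.counts[label].sum())

    def one_vs_rest(self, label: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for the given class treated as positive."""
        c = self.counts
        tp = int(c[label, label])
        fp = int(c[:, label].sum() - tp)
        fn = int(c[label].sum() - tp)
        tn = int(c.sum() - tp - fp - fn)
        return tp, fp, tn, fn


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Tally a 3-class confusion matrix from label vectors."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    bad = (set(y_true.tolist()) | set(y_pred.tolist())) - VALID_LABELS
    if bad:
        raise ValidationError(f"labels outside {sorted(VALID_LABELS)}: {sorted(bad)}")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts)


@dataclass(frozen=True)
class ClassReport:
    """Per-class P/R/F1/E percentages plus micro accuracy and supports.

    ``precision[c]`` is None (and ``f1[c]`` omitted as None) for a class
    with no predicted positives. ``binary_accuracy`` is the per-class
    one-vs-rest accuracy (TP+TN)/total, provided alongside the overall
    micro accuracy.
    """

    precision: tuple[float | None, ...]
    recall: tuple[float, ...]
    f1: tuple[float | None, ...]
    error: tuple[float, ...]
    binary_accuracy: tuple[float, ...]
    accuracy: float
    support: tuple[int, ...]


def class_report(cm: ConfusionMatrix) -> ClassReport:
    """Compute the five evaluation quantities from a confusion matrix."""
    if cm.total < 1:
        raise ValidationError("confusion matrix is empty")
    P: list[float | None] = []
    R: list[float] = []
    F1: list[float | None] = []
    E: list[float] = []
    binacc: list[float] = []
    for label in range(N_CLASSES):
        tp, fp, tn, fn = cm.one_vs_rest(label)
        r = 100.0 * tp / (tp + fn) if tp + fn else 100.0
        r2 = round2(r)
        R.append(r2)
        # derive E from the rounded R so E + R == 100 holds exactly even
        # when the unrounded value sits on a binary-exact half (e.g. 96.875)
        E.append(round2(100.0 - r2))
        binacc.append(round2(100.0 * (tp + tn) / cm.total))
        if tp + fp == 0:
            P.append(None)
            F1.append(None)
            continue
        p = 100.0 * tp / (tp + fp)
        P.append(round2(p))
        F1.append(round2(2 * p * r / (p + r)) if p + r > 0 else 0.0)
    acc = 100.0 * np.trace(cm.counts) / cm.total
    return ClassReport(
        precision=tuple(P),
        recall=tuple(R),
        f1=tuple(F1),
        error=tuple(E),
        binary_accuracy=tuple(binacc),
        accuracy=round2(acc),
        support=tuple(cm.support(c) for c in range(N_CLASSES)),
    )


def f1_from_pr(precision: float, recall: float) -> float:
    """F1 (as a percentage) recomputed from printed P and R percentages."""
    if precision + recall == 0:
        return 0.0
    return round2(2 * precision * recall / (precision + recall))


def report_from_recalls(
    recalls: tuple[float, ...] | list[float],
    supports: tuple[int, ...] | list[int],
) -> float:
    """Reconstruct micro accuracy from per-class recall percentages.

    Each recall must imply an integer number of correct samples within the
    rounding tolerance of a 2-decimal percentage (0.005 * support / 100);
    otherwise the row is internally inconsistent and an error names the
    offending class.
    """
    if len(recalls) != len(supports):
        raise ValidationError("recalls and supports must have equal length")
    correct = 0
    for c, (r, s) in enumerate(zip(recalls, supports)):
        implied = r * s / 100.0
        tol = 0.005 * s / 100.0 + 1e-9
        if abs(implied - round(implied)) > tol:
            raise ValidationError(
                f"class {c} ({ORIGIN_NAMES.get(c, c)}): recall {r}% of "
                f"{s} samples implies a non-integer correct count {implied:.4f}"
            )
        correct += round(implied)
    return round2(100.0 * correct / sum(supports))


def format_report(report: ClassReport) -> str:
    """Text table in the standard column layout.

    Columns: Category, Number, P/%, R/%, F1/%, E/%, Acc/%.
    """
    header = (
        f"{'Category':<12} {'Number':>6} {'P/%':>8} {'R/%':>8} "
        f"{'F1/%':>8} {'E/%':>8} {'Acc/%':>8}"
    )
    lines = [header]
    for c in range(N_CLASSES):
        p = "--" if report.precision[c] is None else f"{report.precision[c]:.2f}"
        f1 = "--" if report.f1[c] is None else f"{report.f1[c]:.2f}"
        acc = f"{report.accuracy:.2f}" if c == 0 else ""
        lines.append(
            f"{c} {'(' + ORIGIN_NAMES[c] + ')':<10} {report.support[c]:>6} "
            f"{p:>8} {report.recall[c]:>8.2f} {f1:>8} "
            f"{report.error[c]:>8.2f} {acc:>8}"
        )
    return "\n".join(lines)
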