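"""Confusion matrices and imbalance-aware classification metrics.

Per-class precision, recall and F1, plus macro (unweighted mean), micro
(pooled TP/FP/FN) and support-weighted averages, and accuracy.  For
single-label multiclass problems micro precision, recall and F1 all equal
accuracy; both micro and weighted rows are emitted because reported tables
in the literature do not always follow the standard micro definition.

Zero-division convention: a class that is never predicted gets precision 0
(with a logged warning) rather than NaN — required for degenerate baselines
such as the constant neutral-only predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_CLASSES = ("positive", "negative", "neutral")

__all__ = [
    "DEFAULT_CLASSES",
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "classification_report",
]


@dataclass
class ConfusionMatrix:
    """Integer counts; rows = true class, columns = predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be a square matrix over the classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> dict[str, int]:
        return {c: int(s) for c, s in zip(self.classes, self.counts.sum(axis=1))}

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(f"pred_{c}" for c in self.classes)]
        for c, row in zip(self.classes, self.counts):
            lines.append(f"true_{c}\t" + "\t".join(str(int(x)) for x in row))
        return "\n".join(lines) + "\n"


def confusion_matrix(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str] = DEFAULT_CLASSES,
) -> ConfusionMatrix:
    """Tally an exhaustive, exclusive confusion matrix in the fixed class
    order.  Unknown labels raise, naming the offender."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"unknown true label: {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label: {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


@dataclass
class EvalReport:
    classes: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    supports: dict[str, int]
    macro: dict[str, float] = field(default_factory=dict)
    micro: dict[str, float] = field(default_factory=dict)
    weighted: dict[str, float] = field(default_factory=dict)
    accuracy: float = 0.0

    def to_tsv(self) -> str:
        lines = ["class\tprecision\trecall\tf1\tsupport"]
        for c in self.classes:
            lines.append(
                f"{c}\t{self.precision[c]:.4f}\t{self.recall[c]:.4f}"
                f"\t{self.f1[c]:.4f}\t{self.supports[c]}"
            )
        for name, row in (
            ("macro-average", self.macro),
            ("micro-average", self.micro),
            ("weighted-average", self.weighted),
        ):
            lines.append(
                f"{name}\t{row['precision']:.4f}\t{row['recall']:.4f}"
                f"\t{row['f1']:.4f}\t{sum(self.supports.values())}"
            )
        lines.append(f"accuracy\t{self.accuracy:.4f}")
        return "\n".join(lines) + "\n"


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def classification_report(cm: ConfusionMatrix) -> EvalReport:
    """Full metric report from a confusion matrix.

    macro = unweighted class mean; micro = pooled TP/FP/FN (equals accuracy
    here); weighted = support-weighted class mean.
    """
    if cm.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    col = counts.sum(axis=0).astype(float)
    row = counts.sum(axis=1).astype(float)

    never_predicted = [c for c, s in zip(cm.classes, col) if s == 0]
    if never_predicted:
        warnings.warn(
            f"classes never predicted, precision set to 0: {never_predicted}",
            stacklevel=2,
        )
    never_true = [c for c, s in zip(cm.classes, row) if s == 0]
    if never_true:
        warnings.warn(
            f"classes with no true examples, recall set to 0: {never_true}",
            stacklevel=2,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        rec = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
    f1 = np.array([_f1(p, r) for p, r in zip(prec, rec)])

    micro_tp = tp.sum()
    micro_fp = (col - tp).sum()
    micro_fn = (row - tp).sum()
    micro_p = micro_tp / (micro_tp + micro_fp) if micro_tp + micro_fp else 0.0
    micro_r = micro_tp / (micro_tp + micro_fn) if micro_tp + micro_fn else 0.0

    weights = row / cm.total
    return EvalReport(
        classes=cm.classes,
        precision={c: float(p) for c, p in zip(cm.classes, prec)},
        recall={c: float(r) for c, r in zip(cm.classes, rec)},
        f1={c: float(x) for c, x in zip(cm.classes, f1)},
        supports=cm.supports,
        macro={
            "precision": float(prec.mean()),
            "recall": float(rec.mean()),
            "f1": float(f1.mean()),
        },
        micro={
            "precision": float(micro_p),
            "recall": float(micro_r),
            "f1": _f1(float(micro_p), float(micro_r)),
        },
        weighted={
            "precision": float(prec @ weights),
            "recall": float(rec @ weights),
            "f1": float(f1 @ weights),
        },
        accuracy=float(tp.sum() / cm.total),
    )
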