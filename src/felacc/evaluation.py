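"""Confusion-matrix construction and agreement metrics.

A :class:`ConfusionMatrix` cross-tabulates observed behaviour labels
(rows) against identified labels (columns). From it the module computes
one-vs-rest per-class metrics (accuracy, precision, sensitivity,
specificity), the micro-averaged overall accuracy, and Cohen's kappa

    kappa = (N * sum_i x_ii - sum_i x_i+ * x_+i) / (N^2 - sum_i x_i+ * x_+i)

which is algebraically the familiar (p_o - p_e) / (1 - p_e). Kappa values
are interpreted on the Fleiss bands: > 0.75 excellent, 0.40-0.75 fair to
good, < 0.40 poor.

Two specificity conventions are offered. ``"standard"`` is
TN / (TN + FP). ``"as_printed"`` (the default) is TN / (TN + FN), the
formula this pipeline historically reported; the two differ whenever
FP != FN for a class, so the mode is part of every metrics report.

Metrics with a zero denominator (e.g. precision of a class never
predicted) are undefined and carried as ``None`` with a flag — never
silently as 0. The one exception is sensitivity with TP = 0 and FN > 0,
which is a true 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

KAPPA_BANDS = ((0.75, "excellent"), (0.40, "fair-to-good"))


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K observed-vs-identified counts.

    ``counts[i, j]`` = number of epochs observed as ``classes[i]`` and
    identified as ``classes[j]``.
    """

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("counts must be K x K for K classes")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        """Observed marginals x_i+."""
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        """Identified marginals x_+i."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest counts and derived proportions for a single class."""

    label: str
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: Optional[float]
    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    undefined: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class KappaResult:
    kappa: Optional[float]
    interpretation: str
    degenerate: bool = False


def confusion_matrix(
    observed: Sequence[str],
    identified: Sequence[str],
    classes: Optional[Sequence[str]] = None,
) -> ConfusionMatrix:
    """Tally observed-vs-identified label pairs into a ConfusionMatrix.

    ``classes`` fixes the row/column order; by default the sorted union
    of labels appearing in either sequence is used.
    """
    obs = list(observed)
    ident = list(identified)
    if len(obs) != len(ident):
        raise ValueError(
            f"length mismatch: {len(obs)} observed vs {len(ident)} identified"
        )
    if classes is None:
        classes = sorted(set(obs) | set(ident))
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(obs) | set(ident)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for o, p in zip(obs, ident):
        counts[index[o], index[p]] += 1
    return ConfusionMatrix(classes, counts)


def class_metrics(
    cm: ConfusionMatrix, mode: str = "as_printed"
) -> list[ClassMetrics]:
    """Per-class one-vs-rest TP/TN/FP/FN and the four derived metrics.

    ``mode`` selects the specificity denominator: ``"standard"`` uses
    TN + FP, ``"as_printed"`` uses TN + FN.
    """
    if mode not in ("standard", "as_printed"):
        raise ValueError(f"unknown metrics mode {mode!r}")
    n = cm.n_total
    out = []
    for i, label in enumerate(cm.classes):
        tp = int(cm.counts[i, i])
        fn = int(cm.row_sums[i] - tp)
        fp = int(cm.col_sums[i] - tp)
        tn = n - tp - fn - fp
        undefined: list[str] = []

        def ratio(num: int, den: int, name: str) -> Optional[float]:
            if den == 0:
                undefined.append(name)
                return None
            return num / den

        acc = ratio(tp + tn, n, "accuracy")
        prec = ratio(tp, tp + fp, "precision")
        sens = ratio(tp, tp + fn, "sensitivity")
        spec_den = tn + (fn if mode == "as_printed" else fp)
        spec = ratio(tn, spec_den, "specificity")
        out.append(ClassMetrics(label, tp, tn, fp, fn, acc, prec, sens, spec,
                                tuple(undefined)))
    return out


def metrics_frame(metrics: Sequence[ClassMetrics]) -> pd.DataFrame:
    """Long per-class metrics table (one row per class)."""
    return pd.DataFrame(
        [
            {
                "behaviour": m.label, "TP": m.tp, "TN": m.tn,
                "FP": m.fp, "FN": m.fn,
                "accuracy": m.accuracy, "precision": m.precision,
                "sensitivity": m.sensitivity, "specificity": m.specificity,
            }
            for m in metrics
        ]
    )


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Micro-averaged overall accuracy: trace / N."""
    n = cm.n_total
    if n == 0:
        raise ValueError("overall accuracy is undefined for an empty matrix")
    return float(np.trace(cm.counts)) / n


def interpret_kappa(kappa: float) -> str:
    for threshold, name in KAPPA_BANDS:
        if kappa > threshold:
            return name
    return "poor"


def cohen_kappa(cm: ConfusionMatrix) -> KappaResult:
    """Chance-corrected agreement between observed and identified labels.

    Returns a degenerate (undefined) result when the chance-agreement
    term equals N^2, which happens when both raters are constant.
    """
    n = cm.n_total
    if n == 0:
        raise ValueError("kappa is undefined for an empty matrix")
    diag = int(np.trace(cm.counts))
    chance = int(np.dot(cm.row_sums, cm.col_sums))
    denom = n * n - chance
    if denom == 0:
        return KappaResult(None, "undefined", degenerate=True)
    kappa = (n * diag - chance) / denom
    return KappaResult(float(kappa), interpret_kappa(kappa))


def intra_rater_kappa(track1, track2) -> KappaResult:
    """Kappa between two annotation passes over the same seconds.

    ``track1`` and ``track2`` are :class:`~felacc.ingestion.AnnotationTrack`
    objects; only the seconds covered by both are compared, and disjoint
    coverage is an error.
    """
    common = sorted(set(track1.seconds()) & set(track2.seconds()))
    if not common:
        raise ValueError("annotation tracks cover disjoint seconds")
    lab1 = track1.labels_for(common)
    lab2 = track2.labels_for(common)
    return cohen_kappa(confusion_matrix(lab1, lab2))
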