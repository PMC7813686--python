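"""Confusion-matrix construction/aggregation and the one-vs-rest metric suite.

Orientation convention (fixed throughout the package): **rows are the
predicted class, columns the actual class**, so column sums are the true
per-class counts.  Per class c, with T the matrix total:

    TP = m[c, c]            FN = column_sum(c) - TP
    FP = row_sum(c) - TP    TN = T - row_sum(c) - column_sum(c) + TP

and the reported quantities are

    Acc = 100 * trace / T            (multi-class accuracy)
    Sen = 100 * TP / (TP + FN)       (sensitivity / recall)
    Spe = 100 * TN / (TN + FP)       (specificity)
    Ppr = 100 * TP / (TP + FP)       (positive prediction rate / precision)

Macro summaries are the mean and the *population* (divide-by-n) standard
deviation over the five per-class values; ``round_first`` first rounds each
per-class value to two decimals, matching how printed summary tables are
derived from printed per-class columns.  Metrics with a zero denominator
are reported as ``None`` (undefined), never coerced to 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_CLASSES = 5


class LabelError(ValueError):
    """A prediction/actual label outside the five known classes."""


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: float | None
    specificity: float | None
    positive_predictivity: float | None


@dataclass
class ConfusionMatrix:
    """5x5 integer counts; rows = predicted, columns = actual."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected 5x5 matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def actual_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)  # column sums

    def predicted_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)  # row sums


def confusion_from_predictions(pred, actual) -> ConfusionMatrix:
    """Tally (predicted, actual) pairs into a 5x5 matrix."""
    pred = np.asarray(pred, dtype=int)
    actual = np.asarray(actual, dtype=int)
    if pred.shape != actual.shape:
        raise ValueError("pred and actual must have equal length")
    if pred.size and (
        pred.min() < 0 or pred.max() >= N_CLASSES or actual.min() < 0 or actual.max() >= N_CLASSES
    ):
        raise LabelError("labels must be class indices 0..4")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (pred, actual), 1)
    return ConfusionMatrix(counts)


def aggregate_folds(per_fold: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Cell-wise sum of per-fold matrices (the integrated confusion matrix)."""
    if not per_fold:
        raise ValueError("no fold matrices to aggregate")
    return ConfusionMatrix(sum(m.counts for m in per_fold))


def _pct(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def per_class_metrics(m: ConfusionMatrix, c: int) -> ClassMetrics:
    """One-vs-rest sensitivity, specificity and positive predictivity (%)."""
    if not 0 <= c < N_CLASSES:
        raise LabelError(f"class index {c} out of range")
    counts = m.counts
    tp = int(counts[c, c])
    col = int(counts[:, c].sum())
    row = int(counts[c, :].sum())
    fn = col - tp
    fp = row - tp
    tn = m.total - row - col + tp
    return ClassMetrics(
        sensitivity=_pct(tp, tp + fn),
        specificity=_pct(tn, tn + fp),
        positive_predictivity=_pct(tp, tp + fp),
    )


def overall_accuracy(m: ConfusionMatrix) -> float:
    """100 * trace / total."""
    if m.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(m.counts)) / m.total


def macro_summary(values, round_first: bool = False) -> tuple[float, float]:
    """Mean and population SD of the five per-class values.

    ``round_first`` rounds each input to 2 decimals before summarising
    (the convention when a summary is derived from a printed table).
    """
    v = np.asarray([x for x in values], dtype=float)
    if v.size != N_CLASSES or np.isnan(v).any():
        raise ValueError("need 5 defined per-class values")
    if round_first:
        v = np.round(v, 2)
    return float(v.mean()), float(v.std())  # ddof=0: population SD


@dataclass
class MetricReport:
    """Full evaluation of one confusion matrix."""

    matrix: ConfusionMatrix
    accuracy: float
    per_class: list[ClassMetrics]
    macro_sensitivity: float
    macro_specificity: float
    macro_positive_predictivity: float
    sd_sensitivity: float
    sd_specificity: float
    sd_positive_predictivity: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": [
                {
                    "sensitivity": c.sensitivity,
                    "specificity": c.specificity,
                    "positive_predictivity": c.positive_predictivity,
                }
                for c in self.per_class
            ],
            "macro": {
                "sensitivity": self.macro_sensitivity,
                "specificity": self.macro_specificity,
                "positive_predictivity": self.macro_positive_predictivity,
            },
            "population_sd": {
                "sensitivity": self.sd_sensitivity,
                "specificity": self.sd_specificity,
                "positive_predictivity": self.sd_positive_predictivity,
            },
        }


def evaluate(m: ConfusionMatrix, round_first: bool = False) -> MetricReport:
    per_class = [per_class_metrics(m, c) for c in range(N_CLASSES)]
    sen = [c.sensitivity for c in per_class]
    spe = [c.specificity for c in per_class]
    ppr = [c.positive_predictivity for c in per_class]
    if any(x is None for x in sen + spe + ppr):
        raise ValueError("macro summary undefined: some per-class metric has a zero denominator")
    msen, ssen = macro_summary(sen, round_first)
    mspe, sspe = macro_summary(spe, round_first)
    mppr, sppr = macro_summary(ppr, round_first)
    return MetricReport(
        matrix=m,
        accuracy=overall_accuracy(m),
        per_class=per_class,
        macro_sensitivity=msen,
        macro_specificity=mspe,
        macro_positive_predictivity=mppr,
        sd_sensitivity=ssen,
        sd_specificity=sspe,
        sd_positive_predictivity=sppr,
    )


def write_matrix_csv(m: ConfusionMatrix, path) -> None:
    np.savetxt(path, m.counts, fmt="%d", delimiter=",")


def read_matrix_csv(path) -> ConfusionMatrix:
    return ConfusionMatrix(np.loadtxt(path, delimiter=",", dtype=np.int64))
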