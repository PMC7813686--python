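"""Confusion-matrix metrics against brute-force counters, an independent
sklearn oracle, and the published benchmark tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import precision_score, recall_score

from ecgbeats.metrics import (
    ConfusionMatrix,
    LabelError,
    aggregate_folds,
    confusion_from_predictions,
    evaluate,
    macro_summary,
    overall_accuracy,
    per_class_metrics,
)
from ecgbeats.reference_tables import (
    BALANCED_COUNTS,
    COMPARED_CNN,
    PROPOSED_CNN,
    RANDOM_FOREST,
)

IDENTITY = ConfusionMatrix(np.eye(5, dtype=int) * 7)


def _brute_force_counts(pred, actual, c):
    tp = sum(1 for p, a in zip(pred, actual) if p == c and a == c)
    fp = sum(1 for p, a in zip(pred, actual) if p == c and a != c)
    fn = sum(1 for p, a in zip(pred, actual) if p != c and a == c)
    tn = sum(1 for p, a in zip(pred, actual) if p != c and a != c)
    return tp, fp, fn, tn


# -- construction ------------------------------------------------------------

def test_diagonal_when_predictions_correct():
    m = confusion_from_predictions([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
    assert np.array_equal(m.counts, np.eye(5, dtype=int))


def test_single_cell_when_all_confused():
    m = confusion_from_predictions([0] * 4, [1] * 4)
    expected = np.zeros((5, 5), dtype=int)
    expected[0, 1] = 4
    assert np.array_equal(m.counts, expected)


def test_matches_brute_force_tally():
    rng = np.random.default_rng(42)
    pred = rng.integers(0, 5, 1000)
    actual = rng.integers(0, 5, 1000)
    m = confusion_from_predictions(pred, actual)
    assert m.total == 1000
    brute = np.zeros((5, 5), dtype=int)
    for p, a in zip(pred, actual):
        brute[p, a] += 1
    assert np.array_equal(m.counts, brute)


def test_label_out_of_range_rejected():
    with pytest.raises(LabelError):
        confusion_from_predictions([0, 5], [0, 0])


def test_orientation_columns_are_actual_counts():
    rng = np.random.default_rng(0)
    actual = np.repeat(np.arange(5), 20)
    pred = rng.integers(0, 5, 100)
    m = confusion_from_predictions(pred, actual)
    assert np.array_equal(m.actual_counts(), [20] * 5)


# -- per-class metrics -------------------------------------------------------

def test_benchmark_cnn_per_class_values():
    m = PROPOSED_CNN.matrix
    c1 = per_class_metrics(m, 0)
    assert round(c1.sensitivity, 2) == 95.41
    assert round(c1.specificity, 2) == 98.15
    # 7216/7677 = 93.9950..., printed (truncated) as 93.99
    assert c1.positive_predictivity == pytest.approx(93.995, abs=5e-4)
    assert round(per_class_metrics(m, 3).sensitivity, 2) == 90.31
    assert round(per_class_metrics(m, 4).positive_predictivity, 2) == 99.51


def test_identity_matrix_gives_perfect_metrics():
    for c in range(5):
        pc = per_class_metrics(IDENTITY, c)
        assert pc.sensitivity == pc.specificity == pc.positive_predictivity == 100.0


def test_per_class_agrees_with_brute_force_and_sklearn():
    rng = np.random.default_rng(7)
    pred = rng.integers(0, 5, 1000)
    actual = rng.integers(0, 5, 1000)
    m = confusion_from_predictions(pred, actual)
    for c in range(5):
        tp, fp, fn, tn = _brute_force_counts(pred, actual, c)
        pc = per_class_metrics(m, c)
        assert pc.sensitivity == pytest.approx(100 * tp / (tp + fn))
        assert pc.specificity == pytest.approx(100 * tn / (tn + fp))
        assert pc.positive_predictivity == pytest.approx(100 * tp / (tp + fp))
        assert tp + fp + fn + tn == m.total
        # independent implementation cross-check
        assert pc.sensitivity == pytest.approx(
            100 * recall_score(actual == c, pred == c, zero_division=0))
        assert pc.positive_predictivity == pytest.approx(
            100 * precision_score(actual == c, pred == c, zero_division=0))


def test_undefined_metric_is_none_not_zero():
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 0] = 10
    m = ConfusionMatrix(counts)
    pc = per_class_metrics(m, 1)
    assert pc.sensitivity is None  # no actual members of class 2
    assert pc.positive_predictivity is None  # never predicted


# -- overall accuracy --------------------------------------------------------

@pytest.mark.parametrize(
    "matrix,expected",
    [(PROPOSED_CNN.matrix, 97.41), (RANDOM_FOREST.matrix, 95.72),
     (COMPARED_CNN.matrix, 94.07), (IDENTITY, 100.0)],
)
def test_overall_accuracy(matrix, expected):
    assert round(overall_accuracy(matrix), 2) == expected


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        overall_accuracy(ConfusionMatrix(np.zeros((5, 5), dtype=int)))


# -- macro summaries ---------------------------------------------------------

def test_macro_mean_of_published_sensitivities():
    mean, _ = macro_summary(PROPOSED_CNN.printed_sensitivity)
    assert round(mean, 2) == 97.05


def test_rounded_first_population_sd_reproduces_published_row():
    _, sd_sen = macro_summary(PROPOSED_CNN.printed_sensitivity, round_first=True)
    _, sd_ppr = macro_summary(
        PROPOSED_CNN.printed_positive_predictivity, round_first=True)
    assert round(sd_sen, 2) == 3.79
    assert round(sd_ppr, 2) == 3.20


def test_equal_values_have_zero_sd():
    mean, sd = macro_summary([88.8] * 5)
    assert mean == pytest.approx(88.8)
    assert sd == 0.0


def test_population_not_sample_sd():
    vals = [90.0, 92.0, 94.0, 96.0, 98.0]
    _, sd = macro_summary(vals)
    assert sd == pytest.approx(np.std(vals))  # ddof=0
    assert sd < np.std(vals, ddof=1)


# -- fold aggregation --------------------------------------------------------

def test_aggregate_is_cellwise_sum():
    agg = aggregate_folds([PROPOSED_CNN.matrix] * 10)
    assert np.array_equal(agg.counts, 10 * PROPOSED_CNN.matrix.counts)
    single = aggregate_folds([PROPOSED_CNN.matrix])
    assert np.array_equal(single.counts, PROPOSED_CNN.matrix.counts)


def test_fold_aggregation_equals_confusion_on_union():
    rng = np.random.default_rng(3)
    pred = rng.integers(0, 5, 600)
    actual = rng.integers(0, 5, 600)
    folds = np.array_split(np.arange(600), 10)
    per_fold = [confusion_from_predictions(pred[f], actual[f]) for f in folds]
    agg = aggregate_folds(per_fold)
    direct = confusion_from_predictions(pred, actual)
    assert np.array_equal(agg.counts, direct.counts)


# -- report ------------------------------------------------------------------

def test_evaluate_report_consistency():
    rep = evaluate(PROPOSED_CNN.matrix)
    assert rep.accuracy == pytest.approx(overall_accuracy(PROPOSED_CNN.matrix))
    assert round(rep.macro_sensitivity, 2) == 97.05
    assert round(rep.macro_specificity, 2) == 99.35
    d = rep.to_dict()
    assert set(d) == {"accuracy", "per_class", "macro", "population_sd"}


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_ovr_counts_always_partition_total(seed):
    rng = np.random.default_rng(seed)
    m = ConfusionMatrix(rng.integers(0, 50, (5, 5)))
    for c in range(5):
        tp = m.counts[c, c]
        row = m.counts[c].sum()
        col = m.counts[:, c].sum()
        tn = m.total - row - col + tp
        assert tp + (row - tp) + (col - tp) + tn == m.total


def test_column_sums_of_benchmark_matrix_match_dataset():
    assert tuple(PROPOSED_CNN.matrix.actual_counts()) == BALANCED_COUNTS
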