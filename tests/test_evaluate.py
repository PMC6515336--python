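import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diliqsar.evaluate import (
    metrics_from_confusion,
    metrics_from_predictions,
    reconstruct_confusion,
    roc_auc,
    y_randomization,
)
from diliqsar.synthetic_fixtures import SyntheticSpec, generate_synthetic_dataset


def auc_pair_oracle(labels, scores):
    """Exhaustive positive-negative pair count, ties worth half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# --- confusion arithmetic ----------------------------------------------------


def test_metric_identities_fuzzed_on_random_tables():
    rng = np.random.default_rng(0)
    tables = rng.integers(0, 500, size=(10_000, 4))
    for tp, fn, tn, fp in tables:
        if tp + fn == 0 or tn + fp == 0:
            continue
        m = metrics_from_confusion(int(tp), int(fn), int(tn), int(fp))
        total = tp + fn + tn + fp
        assert abs(m.acc - (tp + tn) / total) < 1e-12
        assert abs(m.se - tp / (tp + fn)) < 1e-12
        assert abs(m.sp - tn / (tn + fp)) < 1e-12
        assert abs(m.bacc - (m.se + m.sp) / 2) < 1e-12


def test_perfect_classifier_scores_one_everywhere():
    m = metrics_from_confusion(tp=10, fn=0, tn=10, fp=0)
    assert (m.se, m.sp, m.acc, m.bacc) == (1.0, 1.0, 1.0, 1.0)


def test_equal_rates_make_bacc_equal_them():
    m = metrics_from_confusion(tp=30, fn=10, tn=30, fp=10)
    assert m.se == m.sp == m.bacc == 0.75


def test_empty_class_leaves_rate_undefined_but_others_computed():
    m = metrics_from_confusion(tp=0, fn=0, tn=8, fp=2)
    assert math.isnan(m.se) and math.isnan(m.bacc)
    assert m.sp == 0.8 and m.acc == 0.8


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        metrics_from_confusion(-1, 0, 1, 0)


def test_label_swap_exchanges_se_and_sp_exactly():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 200)
    p = rng.integers(0, 2, 200)
    m = metrics_from_predictions(y, p)
    swapped = metrics_from_predictions(1 - y, 1 - p)
    assert swapped.se == m.sp and swapped.sp == m.se
    assert swapped.acc == m.acc


# --- confusion reconstruction ------------------------------------------------


@pytest.mark.parametrize(
    "n_pos,n_neg,se,sp,expected",
    [
        (66, 17, 0.879, 0.647, (58, 8, 11, 6)),
        (58, 27, 0.707, 0.815, (41, 17, 22, 5)),
        (28, 39, 0.786, 0.590, (22, 6, 23, 16)),
        (10, 5, 1.0, 1.0, (10, 0, 5, 0)),
    ],
)
def test_reconstruction_recovers_integer_tables(n_pos, n_neg, se, sp, expected):
    assert reconstruct_confusion(n_pos, n_neg, se, sp) == expected


def test_reconstructed_accuracy_matches_published_style_arithmetic():
    tp, fn, tn, fp = reconstruct_confusion(28, 39, 0.786, 0.590)
    m = metrics_from_confusion(tp, fn, tn, fp)
    assert m.acc == pytest.approx(45 / 67)


def test_out_of_range_rates_rejected():
    with pytest.raises(ValueError):
        reconstruct_confusion(10, 10, 1.2, 0.5)


# --- ROC / AUC ---------------------------------------------------------------


def test_perfectly_separated_scores_give_auc_one():
    roc = roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
    assert roc.auc == 1.0
    assert roc.fpr[0] == 0.0 and roc.tpr[-1] == 1.0


def test_six_point_tie_case_matches_pair_count_oracle():
    labels = [1, 1, 1, 0, 0, 0]
    scores = [0.9, 0.5, 0.4, 0.5, 0.3, 0.1]  # one pos-neg tie at 0.5
    roc = roc_auc(labels, scores)
    assert roc.auc == pytest.approx(auc_pair_oracle(labels, scores), abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    labels=st.lists(st.integers(0, 1), min_size=4, max_size=30),
    data=st.data(),
)
def test_auc_equals_exhaustive_pair_oracle(labels, data):
    if len(set(labels)) < 2:
        labels = labels[:-2] + [0, 1]
    scores = data.draw(
        st.lists(
            st.floats(-5, 5, allow_nan=False),
            min_size=len(labels), max_size=len(labels),
        )
    )
    roc = roc_auc(labels, scores)
    assert roc.auc == pytest.approx(auc_pair_oracle(labels, scores), abs=1e-9)


def test_score_negation_complements_auc_for_tie_free_scores():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    s = rng.standard_normal(100)  # continuous -> tie-free
    assert roc_auc(y, s).auc + roc_auc(y, -s).auc == pytest.approx(1.0, abs=1e-12)


def test_class_swap_maps_auc_to_complement():
    rng = np.random.default_rng(3)
    y = np.r_[np.ones(50, dtype=int), np.zeros(50, dtype=int)]
    s = rng.standard_normal(100)
    assert roc_auc(1 - y, s).auc == pytest.approx(1 - roc_auc(y, s).auc, abs=1e-12)


def test_roc_curve_is_monotone_from_origin_to_one_one():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    roc = roc_auc(y, rng.standard_normal(50))
    assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
    assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
    assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)


def test_single_class_roc_is_fatal():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


# --- Y-randomization ---------------------------------------------------------


def test_y_randomization_returns_chance_level_distribution():
    spec = SyntheticSpec(n=120, n_features=6, signal=2.0, seed=14)
    matrix, y, _ = generate_synthetic_dataset(spec)
    result = y_randomization(matrix.values, y, runs=5, folds=5, seed=3)
    assert result.per_run.shape == (5, 5)
    # even on strongly signaled features, permuted labels give chance ACC
    assert 0.3 < result.mean["ACC"] < 0.7
    assert result.sd["ACC"] >= 0.0


def test_y_randomization_run_count_validation():
    spec = SyntheticSpec(n=40, n_features=4, seed=1)
    matrix, y, _ = generate_synthetic_dataset(spec)
    with pytest.raises(ValueError):
        y_randomization(matrix.values, y, runs=0)
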