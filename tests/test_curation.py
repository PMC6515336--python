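import numpy as np
import pandas as pd
import pytest

from diliqsar.chem_io import CompoundRecord, structure_key
from diliqsar.curation import (
    CurationError,
    CuratedDataset,
    balance_dataset,
    compute_vote_scores,
    kennard_stone_select,
    merge_sources,
    vote_filter,
)
from diliqsar.synthetic_fixtures import SyntheticSpec, generate_synthetic_dataset

from conftest import make_matrix


def rec(cid, smiles, label, tier="tier1"):
    return CompoundRecord(
        cid, smiles, label, source_name="s", source_tier=tier,
        canonical_key=structure_key(smiles),
    )


# --- merge -------------------------------------------------------------------


def test_tier1_label_wins_over_tier2():
    merged = merge_sources(
        [rec("a", "CCO", "positive")], [rec("b", "CCO", "negative", "tier2")]
    )
    active = merged.active
    assert len(active) == 1
    assert active[0].compound_id == "a" and active[0].label == "positive"


def test_tier2_internal_conflict_removed_entirely():
    merged = merge_sources(
        [],
        [rec("a", "CCO", "positive", "tier2"), rec("b", "CCO", "negative", "tier2")],
    )
    assert merged.active == []
    assert all(r.status == "rejected_conflict" for r in merged.records)


def test_disjoint_tiers_union_counts_add():
    merged = merge_sources(
        [rec("a", "CCO", "positive")], [rec("b", "CCN", "negative", "tier2")]
    )
    assert len(merged.active) == 2
    assert merged.provenance() == {"tier1": 1, "tier2": 1}


def test_conflict_within_tier1_fails_loudly():
    with pytest.raises(CurationError, match=structure_key("CCO")):
        merge_sources(
            [rec("a", "CCO", "positive"), rec("b", "CCO", "negative")], []
        )


def test_merge_requires_canonical_keys():
    with pytest.raises(CurationError, match="canonical_key"):
        merge_sources([CompoundRecord("a", "CCO", "positive")], [])


# --- Kennard-Stone -----------------------------------------------------------


def ks_oracle(X, k):
    """Independent max-min selection: plain loops, no vectorization.

    Seeds with the most distant pair (lexicographically smallest on ties),
    then repeatedly adds the candidate with the largest minimum distance to
    the selected set, lowest index on ties.  Distances on z-scored columns.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    def d(i, j):
        return sum((Z[i, c] - Z[j, c]) ** 2 for c in range(Z.shape[1])) ** 0.5

    best, pair = -1.0, None
    for i in range(n):
        for j in range(i + 1, n):
            if d(i, j) > best:
                best, pair = d(i, j), (i, j)
    selected = list(pair)
    while len(selected) < k:
        best, cand = -1.0, None
        for c in range(n):
            if c in selected:
                continue
            mind = min(d(c, s) for s in selected)
            if mind > best:
                best, cand = mind, c
        selected.append(cand)
    return selected


def test_one_dimensional_extremes_selected_first():
    m = make_matrix(np.array([[0.0], [1.0], [10.0]]), ids=["p0", "p1", "p10"])
    assert kennard_stone_select(m, 2) == ["p0", "p10"]


def test_k_equals_n_selects_everything():
    rng = np.random.default_rng(0)
    m = make_matrix(rng.standard_normal((6, 3)))
    assert sorted(kennard_stone_select(m, 6)) == sorted(m.compound_ids)


def test_planted_2d_points_match_stepwise_oracle():
    pts = np.array([[0, 0], [10, 0], [0, 10], [5, 5], [10, 10]], dtype=float)
    m = make_matrix(pts)
    expected = [m.compound_ids[i] for i in ks_oracle(pts, 4)]
    assert kennard_stone_select(m, 4) == expected


@pytest.mark.parametrize("trial", range(20))
def test_matches_exhaustive_oracle_on_random_small_instances(trial):
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(4, 13))
    k = int(rng.integers(2, n + 1))
    X = rng.standard_normal((n, int(rng.integers(1, 5))))
    m = make_matrix(X)
    expected = [m.compound_ids[i] for i in ks_oracle(X, k)]
    assert kennard_stone_select(m, k) == expected


def test_selection_set_is_permutation_equivariant():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((10, 3))  # continuous, ties have probability 0
    m = make_matrix(X)
    picked = set(kennard_stone_select(m, 5))
    perm = rng.permutation(10)
    m2 = make_matrix(X[perm], ids=[m.compound_ids[i] for i in perm])
    assert set(kennard_stone_select(m2, 5)) == picked


@pytest.mark.parametrize("k", [0, 1, 11])
def test_k_out_of_range_is_fatal(k):
    m = make_matrix(np.random.default_rng(0).standard_normal((10, 2)))
    with pytest.raises(ValueError):
        kennard_stone_select(m, k)


def test_duplicate_rows_are_tolerated():
    m = make_matrix(np.array([[0.0], [0.0], [5.0], [5.0]]))
    out = kennard_stone_select(m, 3)
    assert len(out) == 3 and len(set(out)) == 3


# --- balance -----------------------------------------------------------------


def make_labeled_dataset(n_pos, n_neg, seed=0):
    rng = np.random.default_rng(seed)
    records = [
        rec(f"p{i}", f"C{{{i}}}pos", "positive") for i in range(n_pos)
    ] + [rec(f"n{i}", f"C{{{i}}}neg", "negative") for i in range(n_neg)]
    X = rng.standard_normal((n_pos + n_neg, 4))
    m = make_matrix(X, ids=[r.compound_id for r in records])
    return CuratedDataset(records=records), m


def test_balance_reduces_negatives_via_kennard_stone():
    dataset, m = make_labeled_dataset(10, 30)
    out = balance_dataset(dataset, m, target_neg=10)
    n_pos, n_neg = out.class_counts()
    assert (n_pos, n_neg) == (10, 10)
    assert len(out.holdout_negatives) == 20
    neg_ids = [r.compound_id for r in dataset.active if r.label == "negative"]
    expected = set(kennard_stone_select(m.subset_rows(neg_ids), 10))
    kept_neg = {r.compound_id for r in out.active if r.label == "negative"}
    assert kept_neg == expected
    # hold-out pool and modeling set partition the negatives
    holdout = {r.compound_id for r in out.holdout_negatives}
    assert not holdout & {r.compound_id for r in out.active}
    assert holdout | kept_neg == set(neg_ids)


def test_balance_is_noop_with_warning_when_target_too_large():
    dataset, m = make_labeled_dataset(5, 5)
    with pytest.warns(UserWarning, match="no-op"):
        out = balance_dataset(dataset, m, target_neg=10)
    assert out.class_counts() == (5, 5)


# --- vote filter -------------------------------------------------------------


def make_gaussian_dataset(spec):
    matrix, labels, truth = generate_synthetic_dataset(spec)
    records = [
        rec(cid, f"SYN{cid}", "positive" if y == 1 else "negative")
        for cid, y in labels.items()
    ]
    return CuratedDataset(records=records), matrix, labels, truth


def test_vote_filter_threshold_and_monotonicity():
    spec = SyntheticSpec(n=200, n_features=10, signal=1.5, n_informative=4,
                         label_noise=0.05, seed=5)
    dataset, matrix, labels, _ = make_gaussian_dataset(spec)
    filtered, scores = vote_filter(
        dataset, matrix, min_score=2, folds=10, seed=11, profile="small"
    )
    assert scores.between(0, 8).all()
    kept = {r.compound_id for r in filtered.active}
    # exactly the sub-threshold compounds were removed
    assert kept == set(scores.index[scores >= 2])
    assert all(
        r.status == "rejected_vote"
        for r in filtered.records if r.compound_id not in kept
    )
    # removal is monotone in min_score (same seed -> same fold partition)
    stricter, _ = vote_filter(
        dataset, matrix, min_score=4, folds=10, seed=11, profile="small"
    )
    assert {r.compound_id for r in stricter.active} <= kept


def test_vote_filter_keeps_everything_when_all_classifiers_agree():
    spec = SyntheticSpec(n=100, n_features=6, signal=6.0, n_informative=6, seed=2)
    dataset, matrix, _, _ = make_gaussian_dataset(spec)
    filtered, scores = vote_filter(
        dataset, matrix, min_score=2, folds=5, seed=3, profile="small"
    )
    assert (scores >= 7).mean() > 0.95  # near-perfect separation
    assert len(filtered.active) >= 98


def test_flipped_labels_earn_lower_vote_scores():
    spec = SyntheticSpec(n=400, n_features=15, signal=2.0, n_informative=5,
                         label_noise=0.05, seed=17)
    dataset, matrix, labels, truth = make_gaussian_dataset(spec)
    scores = compute_vote_scores(
        matrix.values, labels, folds=10, seed=23, profile="small"
    )
    flipped = scores.loc[truth.flipped_ids]
    clean = scores.drop(truth.flipped_ids)
    assert flipped.mean() < clean.mean()


def test_vote_filter_requires_both_classes():
    spec = SyntheticSpec(n=50, n_features=5, seed=1)
    matrix, labels, _ = generate_synthetic_dataset(spec)
    with pytest.raises(CurationError):
        compute_vote_scores(matrix.values, pd.Series(1, index=labels.index))
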