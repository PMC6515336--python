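"""Dataset assembly: source precedence, Kennard-Stone balancing and the
cross-validated voting mislabel filter.

Sources are split into two trust tiers.  Tier-1 (authoritative,
DILIrank/LiverTox/LTKB-style) labels are kept verbatim; tier-2 compounds
already present in tier 1 are discarded, and tier-2 structures whose own
sources disagree on the label are removed entirely.

Class balance is restored by the Kennard-Stone algorithm: negatives are
reduced to the target count by max-min selection in z-scored descriptor
space, so the retained negatives span the chemical space rather than being
a random draw; the excluded negatives become a held-out reverse-validation
pool.

Finally the voting filter scores every compound by how many of the eight
base classifiers predict it correctly out-of-fold under stratified k-fold
cross-validation (0..8), and compounds scoring below the minimum (default
2) are treated as probable label errors or outliers and dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold

from .chem_io import CompoundRecord
from .descriptors import DescriptorMatrix
from .modeling import (
    CLASSIFIER_ROLES,
    POSITIVE,
    THRESHOLD,
    build_base_classifiers,
)

logger = logging.getLogger(__name__)


class CurationError(ValueError):
    pass


@dataclass
class CuratedDataset:
    """Modeling set plus bookkeeping from merge/balance/vote stages."""

    records: list[CompoundRecord]
    vote_scores: dict[str, int] = field(default_factory=dict)
    holdout_negatives: list[CompoundRecord] = field(default_factory=list)

    @property
    def active(self) -> list[CompoundRecord]:
        return [r for r in self.records if r.is_active]

    @property
    def active_ids(self) -> list[str]:
        return [r.compound_id for r in self.active]

    def labels(self) -> pd.Series:
        """Active labels encoded positive=1 / negative=0."""
        recs = self.active
        bad = [r.compound_id for r in recs if r.label not in ("positive", "negative")]
        if bad:
            raise CurationError(f"unlabeled records in modeling set: {bad[:5]}")
        return pd.Series(
            [1 if r.label == "positive" else 0 for r in recs],
            index=pd.Index([r.compound_id for r in recs], name="compound_id"),
            name="label",
        )

    def class_counts(self) -> tuple[int, int]:
        y = self.labels()
        return int((y == 1).sum()), int((y == 0).sum())

    def provenance(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.active:
            counts[r.source_tier] = counts.get(r.source_tier, 0) + 1
        return counts


def merge_sources(
    tier1: Sequence[CompoundRecord], tier2: Sequence[CompoundRecord]
) -> CuratedDataset:
    """Union of the two tiers under tier-1 precedence.

    * tier-1 records are kept verbatim (first occurrence of a structure key
      wins); a structure carrying both labels WITHIN tier 1 is a curation
      failure and raises, listing the offending keys;
    * tier-2 records whose key appears in tier 1 are discarded;
    * tier-2 keys labeled both positive and negative by different sources
      are removed entirely (conflict), the rest are unioned.
    """
    for rec in list(tier1) + list(tier2):
        if rec.is_active and not rec.canonical_key:
            raise CurationError(
                f"record {rec.compound_id} has no canonical_key; standardize first"
            )

    out: list[CompoundRecord] = []
    t1_labels: dict[str, str] = {}
    t1_conflicts = set()
    for rec in tier1:
        if not rec.is_active:
            out.append(rec)
            continue
        key = rec.canonical_key
        if key in t1_labels:
            if t1_labels[key] != rec.label:
                t1_conflicts.add(key)
            out.append(rec.rejected("rejected_conflict", "duplicate of tier1 structure"))
        else:
            t1_labels[key] = rec.label
            out.append(rec)
    if t1_conflicts:
        raise CurationError(
            "conflicting labels within tier1 for structure keys: "
            + ", ".join(sorted(t1_conflicts))
        )

    # first pass over tier2: find internal label conflicts
    t2_labels: dict[str, set[str]] = {}
    for rec in tier2:
        if rec.is_active and rec.canonical_key not in t1_labels:
            t2_labels.setdefault(rec.canonical_key, set()).add(rec.label)
    t2_conflicts = {k for k, labels in t2_labels.items() if len(labels) > 1}

    seen_t2: set[str] = set()
    for rec in tier2:
        if not rec.is_active:
            out.append(rec)
        elif rec.canonical_key in t1_labels:
            out.append(
                rec.rejected("rejected_conflict", "structure present in tier1")
            )
        elif rec.canonical_key in t2_conflicts:
            out.append(
                rec.rejected("rejected_conflict", "conflicting labels within tier2")
            )
        elif rec.canonical_key in seen_t2:
            out.append(
                rec.rejected("rejected_conflict", "duplicate of tier2 structure")
            )
        else:
            seen_t2.add(rec.canonical_key)
            out.append(rec)
    return CuratedDataset(records=out)


def kennard_stone_select(
    matrix: DescriptorMatrix | pd.DataFrame, k: int
) -> list[str]:
    """Classic Kennard-Stone max-min selection; returns ids in pick order.

    Distances are Euclidean over internally z-scored features (so heavy
    descriptors such as molecular weight do not dominate).  Seeding takes
    the pair at maximum distance; each following pick maximizes the minimum
    distance to the already-selected set.  All ties resolve to the lowest
    row index, which makes the selection fully deterministic.
    """
    df = matrix.values if isinstance(matrix, DescriptorMatrix) else matrix
    n = len(df)
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n={n}, got {k}")
    X = df.to_numpy(dtype=float)
    std = X.std(axis=0)
    keep = std > 0
    Z = np.zeros_like(X)
    Z[:, keep] = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]

    dist = cdist(Z, Z)
    # seed pair: maximum distance; ties -> lexicographically smallest (i, j)
    iu = np.triu_indices(n, k=1)
    flat = dist[iu]
    best = int(np.argmax(flat))  # argmax returns the first (smallest i, then j)
    i, j = int(iu[0][best]), int(iu[1][best])
    selected = [i, j]
    remaining = [r for r in range(n) if r not in (i, j)]
    min_dist = np.minimum(dist[:, i], dist[:, j])
    while len(selected) < k:
        cand = remaining[int(np.argmax(min_dist[remaining]))]
        selected.append(cand)
        remaining.remove(cand)
        min_dist = np.minimum(min_dist, dist[:, cand])
    ids = list(df.index)
    return [ids[s] for s in selected]


def balance_dataset(
    dataset: CuratedDataset, matrix: DescriptorMatrix, target_neg: int
) -> CuratedDataset:
    """Keep all positives; reduce negatives to ``target_neg`` by
    Kennard-Stone selection over the negative-only descriptor rows.

    Excluded negatives are not discarded: they form the held-out
    reverse-validation pool (a negatives-only external check of model
    specificity).
    """
    active = dataset.active
    negatives = [r for r in active if r.label == "negative"]
    if target_neg >= len(negatives):
        warnings.warn(
            f"target_neg={target_neg} >= current negatives ({len(negatives)}); no-op"
        )
        return dataset
    neg_ids = [r.compound_id for r in negatives]
    selected = set(kennard_stone_select(matrix.subset_rows(neg_ids), target_neg))
    kept, holdout = [], []
    for rec in dataset.records:
        if rec.is_active and rec.label == "negative" and rec.compound_id not in selected:
            holdout.append(rec)
        else:
            kept.append(rec)
    return CuratedDataset(
        records=kept,
        vote_scores=dict(dataset.vote_scores),
        holdout_negatives=dataset.holdout_negatives + holdout,
    )


def compute_vote_scores(
    X: pd.DataFrame,
    y: pd.Series,
    folds: int = 10,
    seed: int = 0,
    profile: str = "default",
) -> pd.Series:
    """Out-of-fold correctness votes, 0..8 per compound.

    All eight classifiers share one stratified fold partition; each
    classifier contributes 1 to a compound's score when its out-of-fold
    prediction matches the recorded label.
    """
    y = pd.Series(np.asarray(y, dtype=int), index=X.index)
    if y.nunique() < 2:
        raise CurationError("vote filter needs both classes present")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = pd.Series(0, index=X.index, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train_idx, test_idx in skf.split(X, y):
            X_tr = X.iloc[train_idx].to_numpy(dtype=float)
            y_tr = y.iloc[train_idx].to_numpy()
            X_te = X.iloc[test_idx].to_numpy(dtype=float)
            y_te = y.iloc[test_idx].to_numpy()
            learners = build_base_classifiers(seed, profile)
            for role in CLASSIFIER_ROLES:
                model = learners[role]
                model.fit(X_tr, y_tr)
                proba = model.predict_proba(X_te)
                pos_col = list(model.classes_).index(POSITIVE)
                pred = (proba[:, pos_col] >= THRESHOLD).astype(int)
                scores.iloc[test_idx] += (pred == y_te).astype(int)
    return scores


def vote_filter(
    dataset: CuratedDataset,
    matrix: DescriptorMatrix,
    min_score: int = 2,
    folds: int = 10,
    seed: int = 0,
    profile: str = "default",
) -> tuple[CuratedDataset, pd.Series]:
    """Remove compounds that fewer than ``min_score`` classifiers predict
    correctly out-of-fold — probable label errors and outliers."""
    ids = dataset.active_ids
    X = matrix.subset_rows(ids).values
    y = dataset.labels()
    scores = compute_vote_scores(X, y, folds=folds, seed=seed, profile=profile)
    rejected_ids = set(scores.index[scores < min_score])
    records = [
        rec.rejected(
            "rejected_vote", f"vote score {scores[rec.compound_id]} < {min_score}"
        )
        if rec.is_active and rec.compound_id in rejected_ids
        else rec
        for rec in dataset.records
    ]
    filtered = CuratedDataset(
        records=records,
        vote_scores={cid: int(s) for cid, s in scores.items()},
        holdout_negatives=list(dataset.holdout_negatives),
    )
    logger.info(
        "vote filter removed %d of %d compounds (min_score=%d)",
        len(rejected_ids), len(ids), min_score,
    )
    return filtered, scores


def write_vote_scores(
    scores: pd.Series, min_score: int, path
) -> None:
    df = pd.DataFrame(
        {
            "compound_id": scores.index,
            "score": scores.values,
            "kept": (scores.values >= min_score),
        }
    )
    df.to_csv(path, index=False)
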