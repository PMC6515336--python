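"""The eight base classifiers and the probability-averaging ensemble.

The model is a soft-voting ensemble: eight classifiers of different families
are trained on the retained descriptors, and the positive-class probability
of a compound is the unweighted arithmetic mean of the eight per-classifier
probabilities; the decision threshold is 0.5 with ties called positive
(recognizing hepatotoxins is the stated priority of the endpoint).

Learner roster and hyperparameters mirror the WEKA 3.8 defaults where a
scikit-learn counterpart exists (single-neighbor kNN for IBk, 10 boosting
iterations for AdaBoostM1, 10 bagged trees, 100-tree random forest,
unpruned CART for J48).  Two learners have no open counterpart and are
substituted within the same family:

* ``kstar_like`` — KStar's entropic instance-based learner is replaced by a
  distance-weighted k-nearest-neighbor classifier;
* ``mlp_deep`` — the deep-learning component is replaced by a small
  fully-connected network (one hidden layer, CPU-only).

Every stochastic learner is seeded from one master seed, so a refit with
the same seed reproduces predictions exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_ROLES = (
    "naive_bayes",
    "knn",
    "kstar_like",
    "adaboost",
    "bagging",
    "decision_tree",
    "random_forest",
    "mlp_deep",
)

N_CLASSIFIERS = len(CLASSIFIER_ROLES)

POSITIVE, NEGATIVE = 1, 0
THRESHOLD = 0.5

#: learner sizes: "default" mirrors the WEKA-like defaults; "small" shrinks
#: the expensive learners (forest size, network width/iterations) for
#: many-refit procedures such as Y-randomization, where capacity is
#: irrelevant by construction
PROFILES = ("default", "small")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministically derive n child seeds (< 2**31) from one master."""
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def build_base_classifiers(seed: int, profile: str = "default") -> dict[str, Pipeline]:
    """Instantiate the eight learners, each behind a feature scaler.

    All learners share one z-scoring front end (kNN, naive Bayes and the
    network are scale-sensitive; trees are scale-invariant, so the uniform
    pipeline costs nothing).
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    small = profile == "small"
    seeds = _spawn_seeds(seed, N_CLASSIFIERS)
    learners = {
        "naive_bayes": GaussianNB(),
        "knn": KNeighborsClassifier(n_neighbors=1),
        "kstar_like": KNeighborsClassifier(n_neighbors=5, weights="distance"),
        "adaboost": AdaBoostClassifier(n_estimators=10, random_state=seeds[3]),
        "bagging": BaggingClassifier(
            n_estimators=10,
            max_samples=0.3 if small else 1.0,
            random_state=seeds[4],
        ),
        "decision_tree": DecisionTreeClassifier(random_state=seeds[5]),
        "random_forest": RandomForestClassifier(
            n_estimators=20 if small else 100,
            max_samples=0.5 if small else None,
            random_state=seeds[6],
        ),
        "mlp_deep": MLPClassifier(
            hidden_layer_sizes=(16,) if small else (64,),
            max_iter=50 if small else 300,
            random_state=seeds[7],
        ),
    }
    return {
        role: Pipeline([("scale", StandardScaler()), ("clf", learners[role])])
        for role in CLASSIFIER_ROLES
    }


def ensemble_average(probs: Sequence[float]) -> float:
    """Unweighted mean of the eight per-classifier positive probabilities."""
    if len(probs) != N_CLASSIFIERS:
        raise ValueError(
            f"ensemble averaging needs exactly {N_CLASSIFIERS} probabilities, "
            f"got {len(probs)}"
        )
    probs = np.asarray(probs, dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(probs.mean())


def classify(prob: float, threshold: float = THRESHOLD) -> int:
    """Label from a positive probability; ties at the threshold are positive."""
    return POSITIVE if prob >= threshold else NEGATIVE


def _positive_proba(model: Pipeline, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    pos_col = list(model.classes_).index(POSITIVE)
    return proba[:, pos_col]


@dataclass
class EnsembleModel:
    """Eight fitted base learners plus the averaging rule."""

    base_learners: dict[str, Pipeline]
    feature_names: list[str]
    threshold: float = THRESHOLD
    seed: int | None = None
    profile: str = "default"

    def __post_init__(self) -> None:
        if tuple(self.base_learners) != CLASSIFIER_ROLES:
            raise ValueError(
                f"expected learners {CLASSIFIER_ROLES}, got {tuple(self.base_learners)}"
            )

    def _matrix(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X

    def predict_proba_per_classifier(self, X) -> pd.DataFrame:
        X = self._matrix(X)
        return pd.DataFrame(
            {role: _positive_proba(m, X) for role, m in self.base_learners.items()}
        )

    def predict_proba(self, X) -> np.ndarray:
        per = self.predict_proba_per_classifier(X)
        return per.to_numpy().mean(axis=1)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.where(probs >= self.threshold, POSITIVE, NEGATIVE)


def train_base_classifiers(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    feature_names: Sequence[str] | None = None,
    seed: int = 0,
    profile: str = "default",
) -> EnsembleModel:
    """Fit all eight learners on one training block."""
    y = np.asarray(y, dtype=int)
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = list(feature_names or [f"f{i}" for i in range(X.shape[1])])
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    if not np.isfinite(X).all():
        raise ValueError("training matrix contains missing/non-finite values")
    learners = build_base_classifiers(seed, profile)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for model in learners.values():
            model.fit(X, y)
    return EnsembleModel(learners, feature_names, seed=seed, profile=profile)


@dataclass
class CVResult:
    """Out-of-fold predictions of the ensemble under stratified k-fold CV."""

    fold_assignment: pd.Series            # compound_id -> fold (1-based)
    per_classifier_prob: pd.DataFrame     # compounds x 8 positive probabilities
    ensemble_prob: pd.Series
    predicted_label: pd.Series
    true_label: pd.Series

    def accuracy(self) -> float:
        return float((self.predicted_label == self.true_label).mean())

    def per_classifier_accuracy(self) -> pd.Series:
        preds = (self.per_classifier_prob >= THRESHOLD).astype(int)
        return preds.eq(self.true_label, axis=0).mean()


def save_model(model: EnsembleModel, path) -> None:
    """Persist a fitted ensemble (pickle bundle with a format version)."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump({"format": "diliqsar-ensemble-v1", "model": model}, fh)


def load_model(path) -> EnsembleModel:
    import pickle

    with open(path, "rb") as fh:
        bundle = pickle.load(fh)
    if bundle.get("format") != "diliqsar-ensemble-v1":
        raise ValueError(f"unrecognized model bundle in {path}")
    return bundle["model"]


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[int],
    k: int = 10,
    seed: int = 0,
    profile: str = "default",
) -> CVResult:
    """Stratified k-fold CV of the full eight-learner ensemble.

    Every compound is scored exactly once, by the models of the fold that
    held it out; fold sizes per class differ by at most one.
    """
    y = pd.Series(np.asarray(y, dtype=int), index=X.index)
    if len(X) < k:
        raise ValueError(f"n={len(X)} smaller than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = pd.Series(0, index=X.index, dtype=int)
    per_prob = pd.DataFrame(
        np.nan, index=X.index, columns=list(CLASSIFIER_ROLES), dtype=float
    )
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y), start=1):
        model = train_base_classifiers(
            X.iloc[train_idx], y.iloc[train_idx], seed=seed, profile=profile
        )
        per_prob.iloc[test_idx] = model.predict_proba_per_classifier(
            X.iloc[test_idx]
        ).to_numpy()
        fold_assignment.iloc[test_idx] = fold
    ensemble_prob = per_prob.mean(axis=1)
    predicted = (ensemble_prob >= THRESHOLD).astype(int)
    return CVResult(
        fold_assignment=fold_assignment,
        per_classifier_prob=per_prob,
        ensemble_prob=ensemble_prob,
        predicted_label=predicted,
        true_label=y,
    )
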