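"""Classification metrics, ROC analysis and Y-randomization.

Definitions (TP/TN/FP/FN are confusion counts, positives = hepatotoxic):

    ACC  = (TP + TN) / (TP + TN + FP + FN)
    SE   = TP / (TP + FN)          sensitivity / recall on positives
    SP   = TN / (TN + FP)          specificity / recall on negatives
    BACC = (SE + SP) / 2
    AUC  = P(score_pos > score_neg) + 0.5 P(tie)   (Mann-Whitney form)

AUC is computed two independent ways — by the rank statistic and by the
trapezoidal area under the threshold-sweep ROC curve — and the two must
agree to 1e-9; a discrepancy is a bug, not a rounding issue.

Y-randomization refits the entire cross-validated ensemble on
label-permuted copies of the data (the permutation preserves class counts
by construction) and reports the distribution of the resulting metrics; a
sound model pipeline scores at chance (ACC ~ 0.5 on balanced data) when
the labels carry no information.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .modeling import cross_validate, POSITIVE, NEGATIVE


@dataclass
class EvalMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    se: float
    sp: float
    acc: float
    bacc: float
    auc: float = math.nan

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp,
            "SE": self.se, "SP": self.sp, "ACC": self.acc,
            "BACC": self.bacc, "AUC": self.auc,
        }

    def rounded(self, ndigits: int = 3) -> dict:
        return {
            k: (round(v, ndigits) if isinstance(v, float) and math.isfinite(v) else v)
            for k, v in self.to_dict().items()
        }


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> EvalMetrics:
    """Exact metric arithmetic from confusion counts.

    An empty class leaves the affected rate (and BACC) undefined (NaN);
    the others are still computed.
    """
    for name, v in (("TP", tp), ("FN", fn), ("TN", tn), ("FP", fp)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion table")
    se = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    sp = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    acc = (tp + tn) / total
    bacc = (se + sp) / 2
    return EvalMetrics(tp=tp, fn=fn, tn=tn, fp=fp, se=se, sp=sp, acc=acc, bacc=bacc)


def metrics_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int], scores: Sequence[float] | None = None
) -> EvalMetrics:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE)))
    fn = int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE)))
    tn = int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE)))
    fp = int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE)))
    m = metrics_from_confusion(tp=tp, fn=fn, tn=tn, fp=fp)
    if scores is not None:
        m.auc = roc_auc(y_true, scores).auc
    return m


def reconstruct_confusion(
    n_pos: int, n_neg: int, se: float, sp: float
) -> tuple[int, int, int, int]:
    """Recover integer confusion counts (TP, FN, TN, FP) from printed rates.

    Published comparison tables report class sizes plus SE/SP to a few
    decimals; rounding se*n_pos and sp*n_neg to the nearest integers
    reconstructs the underlying table.  Warns when a printed rate is not
    consistent with any integer count at the given class size.
    """
    if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    tp = round(se * n_pos)
    tn = round(sp * n_neg)
    if abs(tp - se * n_pos) > 0.5 or abs(tn - sp * n_neg) > 0.5:
        warnings.warn("printed rates inconsistent with integer counts")
    return tp, n_pos - tp, tn, n_neg - tn


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> ROCCurve:
    """ROC curve and AUC, with dual-route computation.

    The AUC is the Mann-Whitney rank statistic (ties get half credit); the
    returned curve is the threshold sweep through the distinct scores, whose
    trapezoidal area must agree with the rank statistic to 1e-9.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(labels == POSITIVE))
    n_neg = int(np.sum(labels == NEGATIVE))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis needs both classes present")

    # route 1: rank statistic
    ranks = rankdata(scores)  # average ranks handle ties -> 0.5 credit
    auc_rank = (ranks[labels == POSITIVE].sum() - n_pos * (n_pos + 1) / 2) / (
        n_pos * n_neg
    )

    # route 2: threshold sweep, descending distinct scores
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_labels == POSITIVE)[distinct]
    fps = np.cumsum(sorted_labels == NEGATIVE)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    auc_trap = float(np.trapezoid(tpr, fpr))

    if abs(auc_rank - auc_trap) > 1e-9:
        raise AssertionError(
            f"AUC routes disagree: rank {auc_rank!r} vs sweep {auc_trap!r}"
        )
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(auc_rank))


def metrics_from_cv(cv_result) -> EvalMetrics:
    """Pooled out-of-fold metrics of a cross-validation result."""
    return metrics_from_predictions(
        cv_result.true_label.to_numpy(),
        cv_result.predicted_label.to_numpy(),
        scores=cv_result.ensemble_prob.to_numpy(),
    )


@dataclass
class YRandomizationResult:
    per_run: pd.DataFrame  # runs x {SE, SP, ACC, BACC, AUC}
    mean: pd.Series = field(init=False)
    sd: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.per_run.mean()
        self.sd = self.per_run.std(ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def y_randomization(
    X: pd.DataFrame,
    y: Sequence[int],
    runs: int = 100,
    folds: int = 10,
    seed: int = 0,
    profile: str = "small",
) -> YRandomizationResult:
    """Chance-level reference distribution by label permutation.

    Each run permutes the label vector over the whole set (class counts are
    untouched by construction), reruns the complete stratified k-fold
    ensemble evaluation, and records SE/SP/ACC/BACC/AUC.  The small learner
    profile is the default: on permuted labels there is no signal for model
    capacity to find, and the procedure refits 8 x folds x runs models.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(runs):
        y_perm = rng.permutation(y)
        cv = cross_validate(
            X, y_perm, k=folds, seed=int(rng.integers(2**31)), profile=profile
        )
        m = metrics_from_cv(cv)
        rows.append(
            {"SE": m.se, "SP": m.sp, "ACC": m.acc, "BACC": m.bacc, "AUC": m.auc}
        )
    return YRandomizationResult(per_run=pd.DataFrame(rows))
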