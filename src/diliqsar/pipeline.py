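"""End-to-end orchestration: raw labeled structures to evaluated ensemble.

Stage order: read -> standardize -> descriptors -> merge -> balance ->
feature selection -> vote filter -> cross-validated ensemble -> metrics
(-> optional Y-randomization).  Every stage writes its report into the run
directory and the manifest records record counts at each stage, so
records-in = records-out + records-rejected is checkable end to end.

One master seed fans out to per-stage seeds through a deterministic
derivation (``numpy.random.SeedSequence``), so stages stay independently
reproducible: changing the number of Y-randomization runs does not change
the fold partition of the main cross-validation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    chem_io,
    curation,
    descriptors,
    evaluate,
    feature_select,
    modeling,
    standardize,
)
from .chem_io import CompoundRecord
from .curation import CuratedDataset

logger = logging.getLogger(__name__)

_STAGE_NAMES = (
    "read", "standardize", "descriptors", "merge", "balance",
    "feature_select", "vote_filter", "cross_validate", "evaluate",
    "y_randomization",
)


@dataclass
class PipelineConfig:
    """All pipeline knobs; the defaults are the protocol's stated values."""

    tier1_path: str | None = None
    tier2_path: str | None = None
    output_dir: str = "diliqsar_run"
    near_constant_threshold: float = 0.95
    correlation_cutoff: float = 0.95
    target_negatives: int | None = None  # None -> match the positive count
    vote_min_score: int = 2
    cv_folds: int = 10
    y_randomization_runs: int = 100
    run_y_randomization: bool = False
    learner_profile: str = "default"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        states = ss.generate_state(len(_STAGE_NAMES))
        return {name: int(s) & 0x7FFFFFFF for name, s in zip(_STAGE_NAMES, states)}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    run_dir: Path
    manifest: dict
    metrics: evaluate.EvalMetrics | None = None
    model: modeling.EnsembleModel | None = None
    dataset: CuratedDataset | None = None


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str))


def run_pipeline(
    config: PipelineConfig,
    tier1: list[CompoundRecord] | None = None,
    tier2: list[CompoundRecord] | None = None,
) -> PipelineResult:
    """Execute the full workflow; records may be passed in memory or read
    from the configured paths.  Aborts on the first failing stage, naming
    it and leaving a partial manifest in the run directory."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stage_seeds": seeds,
        "stages": {},
    }
    stage = "read"
    try:
        if tier1 is None:
            if not config.tier1_path:
                raise ValueError("no tier1 records or tier1_path given")
            tier1 = chem_io.read_compound_table(config.tier1_path)
        tier2 = tier2 if tier2 is not None else (
            chem_io.read_compound_table(config.tier2_path) if config.tier2_path else []
        )
        manifest["stages"]["read"] = {"tier1": len(tier1), "tier2": len(tier2)}

        stage = "standardize"
        tier1_std, rep1 = standardize.standardize_dataset(tier1)
        tier2_std, rep2 = standardize.standardize_dataset(tier2)
        (run_dir / "standardization_tier1.json").write_text(rep1.to_json())
        (run_dir / "standardization_tier2.json").write_text(rep2.to_json())
        manifest["stages"]["standardize"] = {
            "in": rep1.input_count + rep2.input_count,
            "passed": rep1.passed + rep2.passed,
            "rejected": (rep1.input_count - rep1.passed)
            + (rep2.input_count - rep2.passed),
        }

        stage = "merge"
        dataset = curation.merge_sources(tier1_std, tier2_std)
        n_pos, n_neg = dataset.class_counts()
        manifest["stages"]["merge"] = {
            "active": len(dataset.active), "positives": n_pos, "negatives": n_neg,
            "rejected_conflict": sum(
                1 for r in dataset.records if r.status == "rejected_conflict"
            ),
        }
        chem_io.write_dataset(dataset.records, run_dir / "merged.csv")

        stage = "descriptors"
        matrix, flagged = descriptors.compute_descriptor_matrix(dataset.active)
        if flagged:
            # a flagged descriptor row cannot enter modeling
            dataset = CuratedDataset(
                records=[
                    r.rejected("rejected_structure", "descriptor computation failed")
                    if r.compound_id in set(flagged) else r
                    for r in dataset.records
                ]
            )
        matrix.to_csv(run_dir / "descriptors.csv")
        manifest["stages"]["descriptors"] = {
            "rows": matrix.shape[0], "features": matrix.shape[1],
            "flagged": len(flagged),
        }

        stage = "balance"
        n_pos, n_neg = dataset.class_counts()
        target = config.target_negatives if config.target_negatives is not None else n_pos
        if n_neg > target:
            dataset = curation.balance_dataset(dataset, matrix, target)
        chem_io.write_dataset(
            dataset.holdout_negatives, run_dir / "reverse_validation_pool.csv"
        )
        n_pos, n_neg = dataset.class_counts()
        manifest["stages"]["balance"] = {
            "positives": n_pos, "negatives": n_neg,
            "holdout_negatives": len(dataset.holdout_negatives),
        }

        stage = "feature_select"
        matrix_active = matrix.subset_rows(dataset.active_ids)
        selected, fs_report = feature_select.select_features(
            matrix_active,
            config.near_constant_threshold,
            config.correlation_cutoff,
        )
        (run_dir / "feature_selection.json").write_text(fs_report.to_json())
        selected.to_csv(run_dir / "descriptors_selected.csv")
        manifest["stages"]["feature_select"] = {
            "in_features": matrix.shape[1],
            "retained_features": selected.shape[1],
        }

        stage = "vote_filter"
        dataset, scores = curation.vote_filter(
            dataset, selected,
            min_score=config.vote_min_score,
            folds=config.cv_folds,
            seed=seeds["vote_filter"],
            profile=config.learner_profile,
        )
        curation.write_vote_scores(
            scores, config.vote_min_score, run_dir / "vote_scores.csv"
        )
        n_pos, n_neg = dataset.class_counts()
        if n_pos == 0 or n_neg == 0:
            raise ValueError(
                f"vote filter (min_score={config.vote_min_score}) left an "
                f"empty class: {n_pos} positives / {n_neg} negatives"
            )
        manifest["stages"]["vote_filter"] = {
            "removed": int((scores < config.vote_min_score).sum()),
            "positives": n_pos, "negatives": n_neg,
        }

        stage = "cross_validate"
        X = selected.subset_rows(dataset.active_ids).values
        y = dataset.labels()
        cv = modeling.cross_validate(
            X, y, k=config.cv_folds, seed=seeds["cross_validate"],
            profile=config.learner_profile,
        )
        cv_out = pd.DataFrame(
            {
                "fold": cv.fold_assignment,
                "ensemble_prob": cv.ensemble_prob,
                "predicted": cv.predicted_label,
                "label": cv.true_label,
            }
        )
        cv_out.join(cv.per_classifier_prob).to_csv(run_dir / "cv_predictions.csv")

        stage = "evaluate"
        metrics = evaluate.metrics_from_cv(cv)
        roc = evaluate.roc_auc(cv.true_label.to_numpy(), cv.ensemble_prob.to_numpy())
        pd.DataFrame(
            {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
        ).to_csv(run_dir / "roc_points.csv", index=False)
        _write_json(run_dir / "metrics.json", metrics.to_dict())
        manifest["stages"]["evaluate"] = metrics.rounded()

        model = modeling.train_base_classifiers(
            X, y, seed=seeds["cross_validate"], profile=config.learner_profile
        )

        if config.run_y_randomization:
            stage = "y_randomization"
            yr = evaluate.y_randomization(
                X, y,
                runs=config.y_randomization_runs,
                folds=config.cv_folds,
                seed=seeds["y_randomization"],
            )
            yr.per_run.to_csv(run_dir / "y_randomization_runs.csv", index=False)
            manifest["stages"]["y_randomization"] = {
                "runs": config.y_randomization_runs,
                "mean": yr.mean.round(3).to_dict(),
                "sd": yr.sd.round(3).to_dict(),
            }

        _write_json(run_dir / "manifest.json", manifest)
        return PipelineResult(
            run_dir=run_dir, manifest=manifest, metrics=metrics,
            model=model, dataset=dataset,
        )
    except PipelineError:
        raise
    except Exception as exc:
        _write_json(run_dir / "manifest.json", manifest)
        raise PipelineError(stage, str(exc)) from exc
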