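"""Scoring, majority-vote consolidation, and the end-to-end experiment.

Each of the five under-sampling subsamples yields one model per fold; the
five fold-models sharing a subsample id are pooled to produce one held-out
prediction per eligible user, scored against the full (imbalanced) class
sizes.  Low-class accuracy is specificity, high-class accuracy sensitivity.
The five per-subsample predictions per user are then consolidated by
majority vote: a user is called high-volatility when at least 3 of the 5
subsample models say so.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import models as mdl
from .errors import ConfigurationError, StageError
from .features import FeatureExtraction, build_feature_matrix
from .resampling import (FoldPlan, TrainingSetGrid, build_training_grid,
                         child_seed, stratified_kfold)
from .selection import SelectionConfig, consensus_select


@dataclass(frozen=True)
class ConfusionSummary:
    n_low: int
    n_high: int
    correct_low: int
    correct_high: int

    @property
    def acc_low(self) -> float:          # specificity
        return self.correct_low / self.n_low if self.n_low else float("nan")

    @property
    def acc_high(self) -> float:         # sensitivity
        return self.correct_high / self.n_high if self.n_high else float("nan")

    @property
    def correct_overall(self) -> int:
        return self.correct_low + self.correct_high

    @property
    def acc_overall(self) -> float:
        return self.correct_overall / (self.n_low + self.n_high)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(acc_low=self.acc_low, acc_high=self.acc_high,
                 acc_overall=self.acc_overall)
        return d


def score(predictions, labels) -> ConfusionSummary:
    """Per-class and overall accuracy of aligned prediction/label vectors."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise ConfigurationError(
            f"length mismatch: {pred.shape} vs {lab.shape}")
    low, high = lab == "low", lab == "high"
    return ConfusionSummary(
        n_low=int(low.sum()), n_high=int(high.sum()),
        correct_low=int((pred[low] == "low").sum()),
        correct_high=int((pred[high] == "high").sum()))


def majority_vote(votes, n_subsamples: int = 5) -> str:
    """Consolidate one user's subsample votes; high needs >= ceil((n+1)/2)."""
    v = np.asarray(votes)
    if v.size != n_subsamples:
        raise ConfigurationError(
            f"expected {n_subsamples} votes, got {v.size}")
    if n_subsamples % 2 == 0:
        raise ConfigurationError("vote count must be odd")
    need = (n_subsamples + 1) // 2
    return "high" if int((v == "high").sum()) >= need else "low"


@dataclass
class SubsampleResult:
    family: str
    feature_set: str
    subsample: int
    predictions: pd.Series            # one held-out prediction per user
    confusion: ConfusionSummary


@dataclass
class ExperimentConfig:
    seed: int = 0
    k_folds: int = 5
    n_subsamples: int = 5
    families: tuple[str, ...] = mdl.FAMILIES
    min_records: int = 5
    rf_n_trees: int = 100
    rf_max_depth: int | None = None
    logreg_cv_folds: int = 5
    #: named feature subsets to evaluate; None -> {"all": every column};
    #: the name "consensus" (with run_selection) is filled by consensus_select
    feature_sets: dict | None = None
    run_selection: bool = False
    selection: SelectionConfig | None = None


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    threshold: float
    class_sizes: dict[str, int]
    subsample_results: list[SubsampleResult]
    consolidated: dict[tuple[str, str], ConfusionSummary]
    consolidated_predictions: dict[tuple[str, str], pd.Series]
    feature_sets: dict[str, tuple[str, ...]]
    selection_report: object = None
    leakage_checked: bool = False
    provenance: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Long-format table mirroring the per-subsample/consolidated layout."""
        rows = []
        for r in self.subsample_results:
            rows.append({"family": r.family, "feature_set": r.feature_set,
                         "row": f"subsample_{r.subsample + 1}",
                         **r.confusion.to_dict()})
        for (fam, fs), conf in self.consolidated.items():
            rows.append({"family": fam, "feature_set": fs,
                         "row": "consolidated", **conf.to_dict()})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "class_sizes": self.class_sizes,
            "feature_sets": {k: list(v) for k, v in self.feature_sets.items()},
            "rows": self.table().to_dict(orient="records"),
            "leakage_checked": self.leakage_checked,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _hash_users(users) -> str:
    return hashlib.sha256("|".join(map(str, sorted(users))).encode()).hexdigest()


def check_leakage(fold_plan: FoldPlan, grid: TrainingSetGrid) -> bool:
    """Every test fold must be disjoint from all its training sets."""
    for (fold, sub), users in grid.entries.items():
        test = set(fold_plan.test_users(fold))
        if test & set(users):
            raise StageError("resampling",
                             f"training set (fold {fold}, sub {sub}) leaks "
                             "test-fold users")
        if _hash_users(test) == _hash_users(users):
            raise StageError("resampling", "test fold equals a training set")
    return True


def _train(family: str, X, y, cfg: ExperimentConfig, seed: int):
    if family == "rf":
        return mdl.train_rf(X, y, n_trees=cfg.rf_n_trees,
                            max_depth=cfg.rf_max_depth, seed=seed)
    if family in ("logreg_ridge", "logreg_lasso"):
        return mdl.train_logreg(X, y, penalty=family.split("_")[1],
                                cv_folds=cfg.logreg_cv_folds, seed=seed)
    raise ConfigurationError(f"unknown model family {family!r}")


def evaluate_feature_sets(X: pd.DataFrame, y: pd.Series, fold_plan: FoldPlan,
                          grid: TrainingSetGrid, cfg: ExperimentConfig,
                          feature_sets: dict[str, tuple[str, ...]]):
    """Train/evaluate every (family, feature set, subsample) combination."""
    check_leakage(fold_plan, grid)
    subsample_results: list[SubsampleResult] = []
    consolidated: dict[tuple[str, str], ConfusionSummary] = {}
    consolidated_pred: dict[tuple[str, str], pd.Series] = {}
    for fs_name, cols in feature_sets.items():
        cols = list(cols)
        for family in cfg.families:
            per_sub: list[pd.Series] = []
            for sub in range(cfg.n_subsamples):
                pred = pd.Series(index=y.index, dtype=object)
                for fold in range(fold_plan.k):
                    train_users = grid.entries[(fold, sub)]
                    s = child_seed(cfg.seed, fold, sub,
                                   zlib.crc32(family.encode()),
                                   zlib.crc32(fs_name.encode()))
                    model = _train(family, X.loc[train_users, cols],
                                   y.loc[train_users], cfg, s)
                    test_users = fold_plan.test_users(fold)
                    pred.loc[test_users] = mdl.predict(
                        model, X.loc[test_users, cols])
                if pred.isna().any():
                    raise StageError("evaluation",
                                     "some users received no prediction")
                per_sub.append(pred)
                subsample_results.append(SubsampleResult(
                    family=family, feature_set=fs_name, subsample=sub,
                    predictions=pred, confusion=score(pred.to_numpy(),
                                                      y.to_numpy())))
            votes = pd.DataFrame({i: p for i, p in enumerate(per_sub)})
            cons = votes.apply(
                lambda row: majority_vote(row.to_numpy(), cfg.n_subsamples),
                axis=1)
            consolidated[(family, fs_name)] = score(cons.to_numpy(),
                                                    y.to_numpy())
            consolidated_pred[(family, fs_name)] = cons
    return subsample_results, consolidated, consolidated_pred


def run_experiment(profiles: pd.DataFrame, records: pd.DataFrame,
                   cfg: ExperimentConfig = ExperimentConfig(),
                   extraction: FeatureExtraction | None = None
                   ) -> ExperimentReport:
    """The full pipeline: extract, label, split, balance, train, consolidate.

    ``extraction`` may be supplied to reuse a precomputed feature matrix (it
    must come from the same cohort).  When ``cfg.run_selection`` is set, the
    consensus feature set is derived from the 25 training sets and evaluated
    alongside the full 132-feature set.
    """
    try:
        ext = extraction or build_feature_matrix(
            profiles, records, min_records=cfg.min_records, seed=cfg.seed)
    except Exception as exc:                      # noqa: BLE001
        if isinstance(exc, StageError):
            raise
        raise StageError("features", str(exc)) from exc

    X, y = ext.X, ext.y
    try:
        fold_plan = stratified_kfold(y, k=cfg.k_folds,
                                     seed=child_seed(cfg.seed, 101))
        grid = build_training_grid(fold_plan, y,
                                   n_subsamples=cfg.n_subsamples,
                                   seed=child_seed(cfg.seed, 202))
    except Exception as exc:                      # noqa: BLE001
        raise StageError("resampling", str(exc)) from exc

    feature_sets: dict[str, tuple[str, ...]] = (
        {k: tuple(v) for k, v in cfg.feature_sets.items()}
        if cfg.feature_sets else {"all": tuple(X.columns)})
    selection_report = None
    if cfg.run_selection:
        sel_cfg = cfg.selection or SelectionConfig(seed=child_seed(cfg.seed, 303))
        try:
            selection_report = consensus_select(X, y, grid, sel_cfg)
        except Exception as exc:                  # noqa: BLE001
            raise StageError("selection", str(exc)) from exc
        if selection_report.selected:
            feature_sets["consensus"] = selection_report.selected

    subsample_results, consolidated, consolidated_pred = evaluate_feature_sets(
        X, y, fold_plan, grid, cfg, feature_sets)

    counts = y.value_counts()
    return ExperimentReport(
        config=cfg, threshold=ext.labeling.threshold,
        class_sizes={"low": int(counts.get("low", 0)),
                     "high": int(counts.get("high", 0))},
        subsample_results=subsample_results, consolidated=consolidated,
        consolidated_predictions=consolidated_pred,
        feature_sets=feature_sets, selection_report=selection_report,
        leakage_checked=True,
        provenance={"seed": cfg.seed, "k_folds": cfg.k_folds,
                    "n_subsamples": cfg.n_subsamples,
                    "min_records": cfg.min_records,
                    "severity_threshold": ext.severity_threshold,
                    "grid_seeds": {f"{k}": v for k, v in grid.seeds.items()}})
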