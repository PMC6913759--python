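"""Stratified cross-validation folds and the 5x5 balanced training-set grid.

Class balance is restored by repeated random under-sampling *within* each
fold's training portion: every balanced set keeps all minority-class users of
the fold's training part and a uniform random, equally sized subset of its
majority-class users.  Test folds are never touched, so evaluation runs on
the full, imbalanced class sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError


def child_seed(master: int, *key: int) -> int:
    """Deterministic sub-seed for a (fold, subsample, ...) coordinate."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class FoldPlan:
    k: int
    fold_ids: pd.Series          # per-user fold id (0..k-1), indexed by user
    seed: int

    def test_users(self, fold: int) -> np.ndarray:
        return self.fold_ids.index[self.fold_ids == fold].to_numpy()

    def train_users(self, fold: int) -> np.ndarray:
        return self.fold_ids.index[self.fold_ids != fold].to_numpy()


@dataclass(frozen=True)
class TrainingSetGrid:
    """Balanced training sets indexed by (fold, subsample)."""

    entries: dict[tuple[int, int], np.ndarray]
    seeds: dict[tuple[int, int], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def manifest(self) -> dict:
        return {
            f"fold{f}_sub{s}": {"seed": self.seeds.get((f, s)),
                                "users": list(map(str, users))}
            for (f, s), users in sorted(self.entries.items())
        }


def stratified_kfold(labels: pd.Series, k: int = 5, seed: int = 0) -> FoldPlan:
    """Assign each user to one of ``k`` stratified test folds."""
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    counts = labels.value_counts()
    if (counts < k).any():
        small = counts[counts < k].index.tolist()
        raise ConfigurationError(f"class(es) {small} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_ids = pd.Series(-1, index=labels.index, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)),
                                                   labels.to_numpy())):
        fold_ids.iloc[test_idx] = fold
    return FoldPlan(k=k, fold_ids=fold_ids, seed=seed)


def random_undersample(labels: pd.Series, seed: int = 0) -> np.ndarray:
    """Balance classes: all minority users + an equal-size random majority subset."""
    counts = labels.value_counts()
    if len(counts) < 2 or counts.min() == 0:
        raise ConfigurationError("both classes must be non-empty")
    minority = counts.idxmin()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    keep_min = labels.index[labels == minority].to_numpy()
    majority_pool = labels.index[labels != minority].to_numpy()
    keep_maj = rng.choice(majority_pool, size=len(keep_min), replace=False)
    return np.concatenate([keep_min, keep_maj])


def build_training_grid(fold_plan: FoldPlan, labels: pd.Series,
                        n_subsamples: int = 5, seed: int = 0) -> TrainingSetGrid:
    """The k x n_subsamples grid of balanced training sets."""
    entries: dict[tuple[int, int], np.ndarray] = {}
    seeds: dict[tuple[int, int], int] = {}
    for fold in range(fold_plan.k):
        train = fold_plan.train_users(fold)
        train_labels = labels.loc[train]
        for sub in range(n_subsamples):
            s = child_seed(seed, fold, sub)
            entries[(fold, sub)] = random_undersample(train_labels, seed=s)
            seeds[(fold, sub)] = s
    return TrainingSetGrid(entries=entries, seeds=seeds)
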