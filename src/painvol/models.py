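"""The three classifier families: random forests and penalised logistic
regression (ridge / lasso).

Random forests use 100 Gini-split trees with floor(sqrt(p)) candidate
features per node; per-node class counts and impurities remain accessible
(``estimator.tree_``) because the Gini importance and Boruta stages consume
them.  Logistic regressions standardise features internally and choose the
penalty strength by cross-validation on the training set only; classification
thresholds sit at probability 0.5, appropriate for the balanced training sets
the resampling stage produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, SchemaMismatchError

FAMILIES = ("logreg_ridge", "logreg_lasso", "rf")
CLASSES = ("low", "high")


@dataclass
class TrainedModel:
    family: str
    estimator: object
    feature_names: tuple[str, ...]
    seed: int
    training_set_id: str = ""

    @property
    def forest(self) -> RandomForestClassifier:
        if self.family != "rf":
            raise ConfigurationError(f"{self.family} model has no forest")
        return self.estimator


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    X = np.asarray(X, dtype=float)
    return X, tuple(f"f{i}" for i in range(X.shape[1]))


def train_rf(X, y, n_trees: int = 100, mtry: int | str = "sqrt",
             seed: int = 0, max_depth: int | None = None) -> TrainedModel:
    """Fit a bootstrap random forest with Gini splitting.

    ``mtry`` defaults to floor(sqrt(p)) candidate features per node.
    """
    if n_trees < 1:
        raise ConfigurationError("n_trees must be >= 1")
    Xm, names = _as_matrix(X)
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features=mtry,
        max_depth=max_depth, bootstrap=True, random_state=seed, n_jobs=1)
    rf.fit(Xm, np.asarray(y))
    return TrainedModel(family="rf", estimator=rf, feature_names=names,
                        seed=seed)


def train_logreg(X, y, penalty: str = "ridge", lambda_grid=None,
                 cv_folds: int = 5, seed: int = 0,
                 max_iter: int = 2000) -> TrainedModel:
    """Penalised logistic regression with internally cross-validated lambda."""
    if penalty not in ("ridge", "lasso"):
        raise ConfigurationError("penalty must be 'ridge' or 'lasso'")
    Xm, names = _as_matrix(X)
    if np.all(np.std(Xm, axis=0) == 0.0):
        raise ConfigurationError("degenerate design: all features constant")
    if lambda_grid is None:
        # lambda from 1e-2 to 1e4 on the standardised scale; weaker
        # penalties than C=1e2 are never selected in practice and make the
        # l1 solver crawl on near-separable training sets
        Cs = np.logspace(-4, 2, 19)
    else:
        Cs = 1.0 / np.asarray(lambda_grid, dtype=float)
    l1 = penalty == "lasso"
    clf = LogisticRegressionCV(
        Cs=Cs, cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        l1_ratios=(1.0,) if l1 else (0.0,),
        solver="liblinear" if l1 else "lbfgs",
        scoring="neg_log_loss",  # deviance-based lambda choice
        tol=1e-3 if l1 else 1e-4,
        max_iter=max_iter, random_state=seed, n_jobs=1)
    pipe = Pipeline([("scale", StandardScaler()), ("logreg", clf)])
    pipe.fit(Xm, np.asarray(y))
    return TrainedModel(family=f"logreg_{penalty}", estimator=pipe,
                        feature_names=names, seed=seed)


def _check_schema(model: TrainedModel, X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if tuple(X.columns) != model.feature_names:
            missing = set(model.feature_names) - set(X.columns)
            extra = set(X.columns) - set(model.feature_names)
            offender = (sorted(missing) or sorted(extra) or ["column order"])[0]
            raise SchemaMismatchError(
                f"feature matrix does not match training schema "
                f"(first offender: {offender})")
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise SchemaMismatchError(
            f"expected {len(model.feature_names)} features, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-matrix'}")
    return X


def _rf_vote_fraction(rf: RandomForestClassifier, Xm: np.ndarray) -> np.ndarray:
    """Fraction of trees whose own prediction is the 'high' class."""
    high_idx = list(rf.classes_).index("high")
    votes = np.zeros(Xm.shape[0])
    for tree in rf.estimators_:
        votes += tree.predict(Xm).astype(int) == high_idx
    return votes / len(rf.estimators_)


def predict(model: TrainedModel, X) -> np.ndarray:
    """Class labels ('low'/'high') for a schema-conforming matrix.

    Forests predict by majority of trees (ties at exactly half go to 'low');
    logistic models threshold the predicted probability at 0.5.
    """
    Xm = _check_schema(model, X)
    if Xm.shape[0] == 0:
        return np.empty(0, dtype=object)
    if model.family == "rf":
        frac = _rf_vote_fraction(model.estimator, Xm)
        return np.where(frac > 0.5, "high", "low")
    return model.estimator.predict(Xm)


def predict_proba_high(model: TrainedModel, X) -> np.ndarray:
    """P(high volatility); for forests, the fraction of trees voting high."""
    Xm = _check_schema(model, X)
    if Xm.shape[0] == 0:
        return np.empty(0, dtype=float)
    est = model.estimator
    if model.family == "rf":
        return _rf_vote_fraction(est, Xm)
    classes = list(est.classes_)
    return est.predict_proba(Xm)[:, classes.index("high")]
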