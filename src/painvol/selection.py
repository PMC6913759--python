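"""Consensus feature selection across the 25 balanced training sets.

Three importance routes feed the consensus rule:

* **Gini importance** — mean decrease in Gini impurity, accumulated from the
  node statistics of a trained random forest.
* **Information gain** — H(Y) - H(Y|X) in bits, continuous features first
  discretised into equal-frequency bins.
* **Boruta** — each feature competes against its own permuted "shadow" copy;
  a feature scores a hit in an iteration when its importance beats the best
  shadow importance, and iterated two-sided binomial tests (Bonferroni
  corrected over the currently undecided features) promote features to
  *important* or demote them to *unimportant*; whatever remains undecided
  after ``max_iter`` iterations is *tentative*.

Per ranking method, a top set is taken in every training set and intersected
across all sets; Boruta contributes the intersection of its per-set important
features.  The final consensus list is the union of the three per-method
sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError
from .models import TrainedModel, train_rf
from .resampling import TrainingSetGrid, child_seed

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# information gain

def equal_frequency_bins(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Discretise a feature into (at most) ``n_bins`` equal-frequency codes.

    Features with <= n_bins distinct values are used as-is.
    """
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, x)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def information_gain(x, y, discretizer=equal_frequency_bins) -> float:
    """H(Y) - H(Y|X) in bits, with X discretised by ``discretizer``."""
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    if classes.size < 2:
        warnings.warn("single-class labels: information gain is 0 by "
                      "convention", stacklevel=2)
        return 0.0
    codes = discretizer(np.asarray(x, dtype=float))
    h_y = _entropy_bits(np.bincount(y_codes))
    n = y_codes.size
    h_y_given_x = 0.0
    for v in np.unique(codes):
        mask = codes == v
        h_y_given_x += mask.sum() / n * _entropy_bits(np.bincount(y_codes[mask]))
    return max(0.0, h_y - h_y_given_x)


# ---------------------------------------------------------------------------
# Gini mean decrease impurity

def _tree_impurity_decrease(tree, n_features: int) -> np.ndarray:
    """Summed weighted impurity decrease per feature for one fitted tree.

    For a split on feature f at node p with children l, r:
        decrease = (w_p * G_p - w_l * G_l - w_r * G_r) / w_root
    accumulated over all of f's splits.
    """
    t = tree.tree_
    imp = np.zeros(n_features)
    w = t.weighted_n_node_samples
    total = w[0]
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        f = t.feature[node]
        dec = (w[node] * t.impurity[node]
               - w[left] * t.impurity[left]
               - w[right] * t.impurity[right]) / total
        imp[f] += dec
    return imp


def gini_importance(model, n_features: int | None = None) -> np.ndarray:
    """Mean decrease in Gini impurity per feature, averaged over a forest.

    ``model`` may be a :class:`TrainedModel` (rf family), a fitted sklearn
    forest, or any iterable of fitted decision trees.
    """
    if isinstance(model, TrainedModel):
        estimators = model.forest.estimators_
        n_features = len(model.feature_names)
    elif isinstance(model, RandomForestClassifier):
        estimators = model.estimators_
        n_features = model.n_features_in_
    else:
        estimators = list(model)
        if n_features is None:
            n_features = estimators[0].tree_.n_features
    if not estimators or not hasattr(estimators[0], "tree_"):
        raise ConfigurationError("need a fitted forest with node statistics")
    acc = np.zeros(n_features)
    for est in estimators:
        acc += _tree_impurity_decrease(est, n_features)
    return acc / len(estimators)


# ---------------------------------------------------------------------------
# Boruta

@dataclass
class _ShadowForest:
    """Small bootstrap forest over [X | shadows] with known OOB sets."""

    n_estimators: int = 40
    max_depth: int | None = 7
    #: bootstrap draw size as a fraction of n (None -> n, the classic choice)
    max_samples: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        n = X.shape[0]
        n_draw = n if self.max_samples is None else max(
            2, int(round(self.max_samples * n)))
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        self.trees_, self.oob_ = [], []
        p = max(1, int(np.floor(np.sqrt(X.shape[1]))))
        for _ in range(self.n_estimators):
            idx = rng.integers(0, n, size=n_draw)
            tree = DecisionTreeClassifier(
                criterion="gini", max_features=p, max_depth=self.max_depth,
                random_state=int(rng.integers(0, 2 ** 31)))
            tree.fit(X[idx], y_codes[idx])
            oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
            self.trees_.append(tree)
            self.oob_.append(oob)
        self._y_codes = y_codes
        return self

    def mdi_importance(self) -> np.ndarray:
        return gini_importance(self.trees_,
                               n_features=self.trees_[0].tree_.n_features)

    def oob_mda_importance(self, X: np.ndarray, rng: np.random.Generator,
                           oob_cap: int | None = None) -> np.ndarray:
        """Z-scored out-of-bag permutation importance (mean decrease in
        accuracy divided by its standard error over trees).

        Features a tree never splits on contribute exactly zero for that
        tree, so only the used features are permuted and re-predicted.
        ``oob_cap`` bounds the number of OOB rows evaluated per tree (a
        random subset), trading Monte-Carlo noise for speed.
        """
        n_features = X.shape[1]
        per_tree = np.zeros((len(self.trees_), n_features))
        for i, (tree, oob) in enumerate(zip(self.trees_, self.oob_)):
            if oob.size == 0:
                continue
            if oob_cap is not None and oob.size > oob_cap:
                oob = rng.choice(oob, size=oob_cap, replace=False)
            Xo = X[oob]
            yo = self._y_codes[oob]
            base = float(np.mean(tree.predict(Xo) == yo))
            used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
            if used.size == 0:
                continue
            # one stacked prediction call for all permuted variants
            stack = np.tile(Xo, (used.size, 1))
            m = Xo.shape[0]
            for j, f in enumerate(used):
                stack[j * m:(j + 1) * m, f] = rng.permutation(Xo[:, f])
            pred = tree.predict(stack).reshape(used.size, m)
            per_tree[i, used] = base - (pred == yo).mean(axis=1)
        mean = per_tree.mean(axis=0)
        se = per_tree.std(axis=0, ddof=1) / np.sqrt(len(self.trees_))
        z = np.zeros(n_features)
        np.divide(mean, se, out=z, where=se > 0)
        return z


@dataclass
class BorutaDecision:
    feature_names: tuple[str, ...]
    status: dict[str, str]            # important / unimportant / tentative
    hits: dict[str, int]
    iterations: int
    alpha: float

    @property
    def important(self) -> frozenset[str]:
        return frozenset(f for f, s in self.status.items() if s == "important")


def boruta(X, y, importance: str = "oob_mda", n_estimators: int = 40,
           max_depth: int | None = 7, max_samples: float | None = None,
           oob_cap: int | None = None, max_iter: int = 30, alpha: float = 0.05,
           seed: int = 0) -> BorutaDecision:
    """Shadow-feature selection around a random forest.

    ``importance`` is ``"oob_mda"`` (out-of-bag permutation accuracy drop,
    the default), ``"mdi"`` (mean decrease impurity) or a callable
    ``f(forest, X_ext, rng) -> importances``.  MDA is the default because a
    feature's chance correlation with the labels is fixed across iterations
    and systematically inflates impurity-based importance over freshly
    permuted shadows, whereas its out-of-bag accuracy contribution does not
    generalise.
    """
    if max_iter < 5:
        raise ConfigurationError("max_iter must be >= 5")
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = tuple(f"f{i}" for i in range(Xm.shape[1]))
    if Xm.shape[1] < 2:
        raise ConfigurationError("need >= 2 features")
    y = np.asarray(y)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # rejected features leave the design (with their shadows); confirmed
    # features stay in it so they keep absorbing the signal, but are no
    # longer tested
    in_system = list(range(Xm.shape[1]))
    undecided = set(in_system)
    hits = np.zeros(Xm.shape[1], dtype=int)
    iters = np.zeros(Xm.shape[1], dtype=int)
    status = np.full(Xm.shape[1], "tentative", dtype=object)
    n_iter_run = 0
    for _ in range(max_iter):
        if not undecided:
            break
        n_iter_run += 1
        Xa = Xm[:, in_system]
        shadows = np.column_stack([rng.permutation(Xa[:, j])
                                   for j in range(Xa.shape[1])])
        X_ext = np.hstack([Xa, shadows])
        forest = _ShadowForest(n_estimators=n_estimators, max_depth=max_depth,
                               max_samples=max_samples).fit(X_ext, y, rng)
        if callable(importance):
            imp = importance(forest, X_ext, rng)
        elif importance == "mdi":
            imp = forest.mdi_importance()
        elif importance == "oob_mda":
            imp = forest.oob_mda_importance(X_ext, rng, oob_cap=oob_cap)
        else:
            raise ConfigurationError(f"unknown importance {importance!r}")
        if not np.all(np.isfinite(imp)):
            raise ConfigurationError("non-finite importances")
        shadow_max = imp[len(in_system):].max()
        for pos, f in enumerate(in_system):
            if f in undecided:
                hits[f] += imp[pos] > shadow_max
                iters[f] += 1

        # two-sided binomial decisions, Bonferroni over undecided features
        n_undecided = len(undecided)
        bonf = alpha / (2 * n_undecided)
        for f in sorted(undecided):
            k, m = hits[f], iters[f]
            p_imp = binom.sf(k - 1, m, 0.5)     # P(X >= k)
            p_rej = binom.cdf(k, m, 0.5)        # P(X <= k)
            if p_imp < bonf:
                status[f] = "important"
                undecided.discard(f)
            elif p_rej < bonf:
                status[f] = "unimportant"
                undecided.discard(f)
                in_system.remove(f)

    return BorutaDecision(
        feature_names=names,
        status={names[i]: str(status[i]) for i in range(len(names))},
        hits={names[i]: int(hits[i]) for i in range(len(names))},
        iterations=n_iter_run, alpha=alpha)


# ---------------------------------------------------------------------------
# per-set rankings and the consensus rule

@dataclass(frozen=True)
class ImportanceRanking:
    method: str                     # "gini" | "info_gain"
    set_id: tuple[int, int]
    feature_names: tuple[str, ...]
    scores: np.ndarray

    @property
    def order(self) -> np.ndarray:
        """Feature indices, best first (ties broken by schema order)."""
        return np.lexsort((np.arange(len(self.scores)), -self.scores))

    def top(self, k: int) -> frozenset[str]:
        return frozenset(self.feature_names[i] for i in self.order[:k])

    def elbow_top(self, min_k: int = 3, max_k: int = 20) -> frozenset[str]:
        """Cut at the largest relative score drop within [min_k, max_k]."""
        s = self.scores[self.order]
        s = np.maximum(s, 1e-12)
        drops = s[:-1] / s[1:]
        lo, hi = min_k - 1, min(max_k, len(s) - 1)
        cut = lo + int(np.argmax(drops[lo:hi])) + 1
        return frozenset(self.feature_names[i] for i in self.order[:cut])


@dataclass(frozen=True)
class SelectionConfig:
    gini_top_k: int = 11
    ig_top_k: int = 8
    top_rule: str = "fixed"             # "fixed" | "elbow"
    ig_bins: int = 10
    gini_n_trees: int = 100
    boruta_importance: str = "oob_mda"
    boruta_n_estimators: int = 25
    boruta_max_depth: int | None = 6
    boruta_max_samples: float | None = 0.5
    boruta_oob_cap: int | None = 120
    boruta_max_iter: int = 25
    boruta_alpha: float = 0.05
    seed: int = 0


@dataclass
class ConsensusReport:
    per_method_common: dict[str, frozenset[str]]
    selected: tuple[str, ...]
    per_set: list[dict] = field(default_factory=list)
    config: SelectionConfig | None = None

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "per_method_common": {m: sorted(s) for m, s
                                  in self.per_method_common.items()},
            "n_sets": len({r["set_id"] for r in self.per_set}),
        }

    def rankings_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.per_set:
            for rank, (feat, score) in enumerate(rec.get("ranking", []), 1):
                rows.append({"set_id": str(rec["set_id"]),
                             "method": rec["method"], "feature": feat,
                             "score": score, "rank": rank})
        return pd.DataFrame(rows)


def consensus_select(X: pd.DataFrame, y: pd.Series, grid: TrainingSetGrid,
                     config: SelectionConfig = SelectionConfig()) -> ConsensusReport:
    """Apply all three selection methods to every training set and combine.

    Per method, the features found important in *all* training sets are kept;
    the final list is the union over methods (schema column order).
    """
    names = tuple(X.columns)
    per_set: list[dict] = []
    method_sets: dict[str, list[frozenset[str]]] = {
        "gini": [], "info_gain": [], "boruta": []}

    for (fold, sub), users in sorted(grid.entries.items()):
        Xs, ys = X.loc[users], y.loc[users]
        s = child_seed(config.seed, fold, sub)

        model = train_rf(Xs, ys, n_trees=config.gini_n_trees, seed=s)
        g = ImportanceRanking("gini", (fold, sub), names,
                              gini_importance(model))
        gset = (g.elbow_top() if config.top_rule == "elbow"
                else g.top(config.gini_top_k))
        method_sets["gini"].append(gset)

        ig_scores = np.array([
            information_gain(Xs[c], ys,
                             discretizer=lambda v: equal_frequency_bins(
                                 v, config.ig_bins))
            for c in names])
        ig = ImportanceRanking("info_gain", (fold, sub), names, ig_scores)
        igset = (ig.elbow_top() if config.top_rule == "elbow"
                 else ig.top(config.ig_top_k))
        method_sets["info_gain"].append(igset)

        dec = boruta(Xs, ys, importance=config.boruta_importance,
                     n_estimators=config.boruta_n_estimators,
                     max_depth=config.boruta_max_depth,
                     max_samples=config.boruta_max_samples,
                     oob_cap=config.boruta_oob_cap,
                     max_iter=config.boruta_max_iter,
                     alpha=config.boruta_alpha, seed=s)
        method_sets["boruta"].append(dec.important)

        order = g.order
        per_set += [
            {"set_id": (fold, sub), "method": "gini",
             "top": sorted(gset),
             "ranking": [(names[i], float(g.scores[i])) for i in order[:20]]},
            {"set_id": (fold, sub), "method": "info_gain",
             "top": sorted(igset),
             "ranking": [(names[i], float(ig.scores[i]))
                         for i in ig.order[:20]]},
            {"set_id": (fold, sub), "method": "boruta",
             "top": sorted(dec.important)},
        ]

    common: dict[str, frozenset[str]] = {}
    for method, sets in method_sets.items():
        inter = frozenset(names).intersection(*sets) if sets else frozenset()
        if not inter:
            log.info("method %s: empty intersection across %d sets",
                     method, len(sets))
        common[method] = inter
    union = frozenset().union(*common.values())
    selected = tuple(n for n in names if n in union)
    return ConsensusReport(per_method_common=common, selected=selected,
                           per_set=per_set, config=config)
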