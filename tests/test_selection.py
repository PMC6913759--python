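"""Information gain, Gini importance, Boruta, and the consensus rule."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

import painvol as pv
from painvol.errors import ConfigurationError
from painvol.resampling import TrainingSetGrid
from painvol.selection import (ImportanceRanking, _ShadowForest,
                               equal_frequency_bins)

from _oracles import forest_total_impurity_decrease, ig_oracle


# --- information gain -------------------------------------------------------

def test_ig_of_label_copy_is_one_bit():
    y = np.array(["low", "high"] * 50)
    x = (y == "high").astype(float)
    assert pv.information_gain(x, y) == pytest.approx(1.0)


def test_ig_eight_sample_worked_example():
    """Balanced 8-sample label; feature splits into (3 low, 1 high) and
    (1 low, 3 high): IG = 1 - 0.8113 = 0.1887 bits."""
    y = np.array(["low"] * 4 + ["high"] * 4)
    x = np.array([0, 0, 0, 1, 0, 1, 1, 1], dtype=float)
    assert pv.information_gain(x, y) == pytest.approx(0.18872, abs=1e-4)


def test_ig_matches_entropy_oracle_on_random_tables():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = int(rng.integers(10, 80))
        x = rng.integers(0, int(rng.integers(2, 6)), n).astype(float)
        y = np.where(rng.random(n) < 0.5, "high", "low")
        if np.unique(y).size < 2:
            continue
        got = pv.information_gain(x, y)
        want = ig_oracle(x.astype(int), y)
        assert got == pytest.approx(max(0.0, want), abs=1e-10)
        assert 0.0 <= got <= 1.0 + 1e-12


def test_ig_independent_feature_near_zero():
    rng = np.random.default_rng(12)
    n = 500
    x = rng.normal(size=n)
    y = np.where(rng.random(n) < 0.5, "high", "low")
    assert pv.information_gain(x, y) < 0.02


def test_ig_single_class_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert pv.information_gain(np.arange(6.0), ["low"] * 6) == 0.0


def test_equal_frequency_bins_limits_cardinality():
    rng = np.random.default_rng(1)
    x = rng.exponential(size=1000)  # heavy tailed
    codes = equal_frequency_bins(x, n_bins=10)
    _, counts = np.unique(codes, return_counts=True)
    assert len(counts) == 10
    assert counts.max() <= 2 * counts.min()  # roughly equal occupancy
    binary = np.array([0.0, 1.0] * 20)
    assert set(equal_frequency_bins(binary)) == {0, 1}


# --- Gini importance --------------------------------------------------------

def test_stump_importance_is_half_for_pure_split():
    """A balanced node split into two pure children loses impurity 0.5."""
    X = np.array([[0, 7], [0, 3], [0, 9], [0, 1],
                  [1, 2], [1, 8], [1, 4], [1, 6]], dtype=float)
    y = np.array(["low"] * 4 + ["high"] * 4)
    stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
    imp = pv.gini_importance([stump])
    assert imp[0] == pytest.approx(0.5)
    assert imp[1] == 0.0


def test_unused_feature_scores_zero(labeled_frame):
    X, y = labeled_frame
    X = X.copy()
    X["constant"] = 1.0
    model = pv.train_rf(X, y, n_trees=30, seed=0)
    imp = pv.gini_importance(model)
    assert imp[list(X.columns).index("constant")] == 0.0


def test_importance_sums_to_total_impurity_decrease(labeled_frame):
    """Conservation: per-forest importance total equals the telescoped
    root-minus-leaves impurity decrease, every run."""
    X, y = labeled_frame
    for seed in range(5):
        model = pv.train_rf(X, y, n_trees=25, seed=seed)
        imp = pv.gini_importance(model)
        total = forest_total_impurity_decrease(model.forest.estimators_)
        assert imp.sum() == pytest.approx(total, rel=1e-9)
        assert (imp >= 0).all()


def test_matches_sklearn_mdi_up_to_normalisation(labeled_frame):
    X, y = labeled_frame
    model = pv.train_rf(X, y, n_trees=40, seed=3)
    mine = pv.gini_importance(model)
    sk = model.forest.feature_importances_
    # sklearn normalises per tree before averaging; agreement is close but
    # not bitwise
    assert np.allclose(mine / mine.sum(), sk, atol=0.01)
    assert np.argmax(mine) == np.argmax(sk)


def test_planted_feature_ranked_first():
    rng = np.random.default_rng(0)
    wins = 0
    for s in range(20):
        y = np.where(rng.random(400) < 0.5, "high", "low")
        X = pd.DataFrame(rng.normal(size=(400, 51)),
                         columns=[f"f{i}" for i in range(51)])
        X["f0"] += (y == "high") * 1.5
        model = pv.train_rf(X, pd.Series(y), n_trees=50, seed=s)
        wins += int(np.argmax(pv.gini_importance(model)) == 0)
    assert wins >= 19


def test_unfitted_input_rejected():
    with pytest.raises((ConfigurationError, IndexError)):
        pv.gini_importance([])


# --- Boruta -----------------------------------------------------------------

def _copy_plus_noise(n=300, p_noise=10, seed=0):
    rng = np.random.default_rng(seed)
    y = np.where(rng.random(n) < 0.5, "high", "low")
    X = pd.DataFrame(rng.normal(size=(n, p_noise + 1)),
                     columns=["copy"] + [f"noise{i}" for i in range(p_noise)])
    X["copy"] = (y == "high").astype(float)
    return X, y


@pytest.mark.parametrize("importance", ["mdi", "oob_mda"])
def test_boruta_finds_label_copy(importance):
    X, y = _copy_plus_noise(seed=4)
    dec = pv.boruta(X, y, importance=importance, max_iter=50, seed=1)
    assert dec.status["copy"] == "important"


def test_boruta_all_noise_mostly_rejected():
    rng = np.random.default_rng(9)
    false_imp = 0
    for s in range(5):
        y = np.where(rng.random(300) < 0.5, "high", "low")
        X = pd.DataFrame(rng.normal(size=(300, 12)))
        X.columns = [f"f{i}" for i in range(12)]
        dec = pv.boruta(X, y, max_iter=40, seed=s)
        false_imp += len(dec.important)
    assert false_imp <= 1


def test_boruta_too_few_iterations_leaves_all_tentative():
    X, y = _copy_plus_noise(seed=2)
    dec = pv.boruta(X, y, max_iter=5, seed=0)
    assert set(dec.status.values()) == {"tentative"}
    assert dec.iterations == 5


def test_boruta_hit_counts_bounded_by_iterations():
    X, y = _copy_plus_noise(seed=3)
    dec = pv.boruta(X, y, max_iter=20, seed=0)
    assert all(0 <= h <= dec.iterations for h in dec.hits.values())


def test_boruta_requires_two_features():
    with pytest.raises(ConfigurationError):
        pv.boruta(np.ones((20, 1)), ["low", "high"] * 10)


def test_shadow_forest_oob_mda_zero_for_unused_features():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 6))
    y = np.where(X[:, 0] > 0, "high", "low")
    X[:, 5] = 0.0  # constant -> never split on
    f = _ShadowForest(n_estimators=20, max_depth=4).fit(
        X, np.asarray(y), rng)
    imp = f.oob_mda_importance(X, rng)
    assert imp[5] == 0.0
    assert imp[0] == imp.max() > 0.1


# --- consensus --------------------------------------------------------------

def _toy_grid(X, y, n_folds=2, n_subs=2):
    entries = {}
    rng = np.random.default_rng(0)
    for f in range(n_folds):
        for s in range(n_subs):
            entries[(f, s)] = rng.choice(X.index, size=int(0.8 * len(X)),
                                         replace=False)
    return TrainingSetGrid(entries=entries)


def test_consensus_union_of_per_method_sets(labeled_frame):
    X, y = labeled_frame
    grid = _toy_grid(X, y)
    cfg = pv.SelectionConfig(gini_top_k=3, ig_top_k=2, boruta_max_iter=15,
                             seed=0)
    rep = pv.consensus_select(X, y, grid, cfg)
    union = frozenset().union(*rep.per_method_common.values())
    assert frozenset(rep.selected) == union
    assert "f0" in rep.selected          # the planted signal feature
    for sets in rep.per_method_common.values():
        assert sets <= frozenset(X.columns)


def test_consensus_order_invariant(labeled_frame):
    X, y = labeled_frame
    grid = _toy_grid(X, y)
    reordered = TrainingSetGrid(entries=dict(reversed(list(grid.entries.items()))))
    cfg = pv.SelectionConfig(gini_top_k=3, ig_top_k=2, boruta_max_iter=15,
                             seed=0)
    a = pv.consensus_select(X, y, grid, cfg)
    b = pv.consensus_select(X, y, reordered, cfg)
    assert a.selected == b.selected


def test_union_size_with_overlapping_method_sets():
    """Per-method sets of sizes 8, 5 and 4 whose overlaps leave 9 distinct
    features behave as a plain set union."""
    gini = frozenset("ABCDEFGH")          # 8
    ig = frozenset("ACDFI")               # 5, adds I
    bor = frozenset("ACDF")               # 4, adds nothing
    assert len(gini | ig | bor) == 9


def test_elbow_rule_cuts_at_largest_relative_drop():
    scores = np.array([10.0, 9.0, 8.5, 0.5, 0.4, 0.3, 0.2, 0.1])
    r = ImportanceRanking("gini", (0, 0),
                          tuple(f"f{i}" for i in range(8)), scores)
    assert r.elbow_top(min_k=2, max_k=6) == frozenset({"f0", "f1", "f2"})
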