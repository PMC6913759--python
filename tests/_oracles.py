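"""Independent brute-force oracles used to check the implementation.

Each oracle recomputes a quantity directly from its defining formula (or by
exhaustive enumeration), staying independent of the code paths it checks.
"""

from __future__ import annotations

import numpy as np


def brute_volatility(ratings) -> float:
    """Mean absolute consecutive change via an explicit loop."""
    total = 0.0
    n = len(ratings)
    for i in range(1, n):
        total += abs(ratings[i] - ratings[i - 1])
    return total / (n - 1)


def brute_trend_delta(times, ratings) -> tuple[float, float]:
    """OLS trend rise via statsmodels, slope * (t_n - t_1)."""
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(times, dtype=float))
    fit = sm.OLS(np.asarray(ratings, dtype=float), X).fit()
    delta = float(fit.params[1] * (times[-1] - times[0]))
    return delta, abs(delta)


def dp_two_means(values) -> tuple[float, np.ndarray]:
    """Exact 1-D 2-means by enumerating every split of the sorted values.

    The optimal 2-cluster partition in one dimension is a split of the sorted
    sequence, so trying all n-1 splits finds the global within-cluster
    sum-of-squares optimum.  Returns (best SSE, boolean high-cluster mask in
    the original order).
    """
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    s = v[order]
    n = s.size
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    best_sse, best_i = np.inf, 1
    for i in range(1, n):  # low cluster = s[:i]
        sse_lo = csq[i - 1] - csum[i - 1] ** 2 / i
        sse_hi = (csq[-1] - csq[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        sse = sse_lo + sse_hi
        if sse < best_sse - 1e-12:
            best_sse, best_i = sse, i
    high = np.zeros(n, dtype=bool)
    high[order[best_i:]] = True
    return float(best_sse), high


def dp_two_means_threshold(values) -> float:
    """Boundary-gap midpoint of the exact 1-D 2-means partition."""
    v = np.asarray(values, dtype=float)
    _, high = dp_two_means(v)
    return float((v[~high].max() + v[high].min()) / 2.0)


def entropy_bits(labels) -> float:
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def ig_oracle(x_codes, y) -> float:
    """H(Y) - H(Y|X) by direct entropy arithmetic over discrete codes."""
    x_codes = np.asarray(x_codes)
    y = np.asarray(y)
    h = entropy_bits(y)
    for v in np.unique(x_codes):
        mask = x_codes == v
        h -= mask.mean() * entropy_bits(y[mask])
    return h


def brute_vote(votes, need_high: int = 3) -> str:
    """Count 'high' votes with a plain loop."""
    n_high = 0
    for v in votes:
        if v == "high":
            n_high += 1
    return "high" if n_high >= need_high else "low"


def forest_total_impurity_decrease(estimators) -> float:
    """Mean over trees of (root impurity - weighted leaf impurity) / root n.

    Telescoping over the tree: the total impurity decrease accumulated by all
    splits equals the root's weighted impurity minus the weighted sum of the
    leaves' impurities.  This is an independent route to the quantity the
    per-feature Gini importances must sum to.
    """
    totals = []
    for est in estimators:
        t = est.tree_
        w = t.weighted_n_node_samples
        leaves = t.children_left == -1
        leaf_impurity = float((w[leaves] * t.impurity[leaves]).sum())
        totals.append((w[0] * t.impurity[0] - leaf_impurity) / w[0])
    return float(np.mean(totals))
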