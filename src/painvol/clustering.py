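"""Low/high volatility class boundary via one-dimensional 2-means.

Volatility values from both observation windows are pooled and split into two
clusters; the class boundary is the midpoint between the largest value of the
low cluster and the smallest value of the high cluster, so that thresholding
at it reproduces the cluster assignment exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import ConfigurationError, DegenerateClusteringError


@dataclass(frozen=True)
class VolatilityLabeling:
    threshold: float
    centroids: tuple[float, float]          # (low, high)
    assignments: np.ndarray                 # "low"/"high" per input value

    def classify(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return np.where(v >= self.threshold, "high", "low")


@dataclass(frozen=True)
class ThresholdValidation:
    thresholds: tuple[float, ...]
    mean: float
    sd: float
    range: tuple[float, float]


def kmeans_threshold(values, seed: int = 0, n_init: int = 25) -> VolatilityLabeling:
    """2-means on pooled 1-D values; threshold at the boundary-gap midpoint."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2 or np.unique(v).size < 2:
        raise DegenerateClusteringError(
            "need at least two distinct values for a 2-cluster split")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    labels = km.fit_predict(v.reshape(-1, 1))
    cents = km.cluster_centers_.ravel()
    low_cluster = int(np.argmin(cents))
    low_max = v[labels == low_cluster].max()
    high_min = v[labels != low_cluster].min()
    threshold = float((low_max + high_min) / 2.0)
    assignments = np.where(v >= threshold, "high", "low")
    return VolatilityLabeling(threshold=threshold,
                              centroids=(float(cents.min()), float(cents.max())),
                              assignments=assignments)


def validate_threshold(values, n_subsamples: int = 20, frac: float = 0.5,
                       seed: int = 0, n_init: int = 25) -> ThresholdValidation:
    """Re-derive the threshold on random subsamples and summarise dispersion."""
    if not 0.0 < frac <= 1.0:
        raise ConfigurationError("frac must be in (0, 1]")
    v = np.asarray(values, dtype=float).ravel()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m = max(2, int(round(frac * v.size)))
    thresholds = []
    for i in range(n_subsamples):
        sub = rng.choice(v, size=m, replace=False)
        if np.unique(sub).size < 2:
            warnings.warn(f"subsample {i}: fewer than two distinct values; "
                          "skipped", stacklevel=2)
            continue
        thresholds.append(kmeans_threshold(sub, seed=seed, n_init=n_init).threshold)
    t = np.asarray(thresholds)
    return ThresholdValidation(
        thresholds=tuple(float(x) for x in t),
        mean=float(t.mean()), sd=float(t.std(ddof=1)) if t.size > 1 else 0.0,
        range=(float(t.min()), float(t.max())))
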