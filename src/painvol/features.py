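"""Per-user feature extraction from raw pain records.

The predictor window covers days 0-29 from a user's first record; the outcome
window covers days 150-179.  Users enter the analysis only with at least
``min_records`` records in *both* windows.  Each eligible user is represented
by a 132-dimensional vector (see :mod:`painvol.schema`), whose pain-statistics
block contains the volatility statistic

    volatility = (1/(n-1)) * sum_i |r_i - r_{i-1}|

computed over the date-ordered severity ratings of a window, together with
its standard deviation, the ratings' mean/SD, the rise of an OLS trend line
over the window, and two dichotomised level features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema as sc
from .clustering import VolatilityLabeling, kmeans_threshold
from .errors import (ConfigurationError, DegenerateFitError,
                     UndefinedVolatilityError)

log = logging.getLogger(__name__)

PREDICTOR = "predictor"
OUTCOME = "outcome"
#: inclusive day-offset ranges relative to the user's first record
WINDOW_RANGES = {PREDICTOR: (0, 29), OUTCOME: (150, 179)}


def compute_volatility(ratings) -> float:
    """Mean absolute change between consecutive severity ratings."""
    r = np.asarray(ratings, dtype=float)
    if r.size < 2:
        raise UndefinedVolatilityError(
            f"need >=2 ratings, got {r.size}")
    return float(np.mean(np.abs(np.diff(r))))


def volatility_sd(ratings) -> float:
    """Sample SD of the absolute consecutive changes (0 when only one change)."""
    r = np.asarray(ratings, dtype=float)
    if r.size < 2:
        raise UndefinedVolatilityError(f"need >=2 ratings, got {r.size}")
    d = np.abs(np.diff(r))
    return float(np.std(d, ddof=1)) if d.size > 1 else 0.0


def trend_delta(times, ratings) -> tuple[float, float]:
    """Rise of the OLS trend line over the observation span.

    Returns ``(delta, |delta|)`` where delta = fitted value at the last time
    minus fitted value at the first, i.e. slope * (t_n - t_1).
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(ratings, dtype=float)
    if t.size < 2:
        raise DegenerateFitError("need >=2 records")
    span = t.max() - t.min()
    if span == 0:
        raise DegenerateFitError("all record times identical")
    slope = np.polyfit(t, r, 1)[0]
    delta = float(slope * (t[-1] - t[0]))
    return delta, abs(delta)


def assign_windows(records: pd.DataFrame) -> pd.DataFrame:
    """Tag each record with its window (or drop it if outside both).

    Adds ``day`` (offset from the user's first record) and ``window``
    columns; records outside the two 30-day windows are removed.  Row order
    within (user, date) ties is preserved, so repeated same-day entries stay
    consecutive ratings.
    """
    rec = records.copy()
    dates = pd.to_datetime(rec["date"])
    rec["day"] = (dates - dates.groupby(rec["user_id"]).transform("min")).dt.days
    rec["window"] = pd.Series(pd.NA, index=rec.index, dtype="object")
    for win, (lo, hi) in WINDOW_RANGES.items():
        rec.loc[rec["day"].between(lo, hi), "window"] = win
    rec = rec[rec["window"].notna()]
    return rec.sort_values(["user_id", "day"], kind="stable").reset_index(drop=True)


def filter_users(windowed: pd.DataFrame, min_records: int = 5) -> np.ndarray:
    """Users with at least ``min_records`` records in both windows."""
    counts = (windowed.groupby(["user_id", "window"]).size()
              .unstack(fill_value=0))
    for win in (PREDICTOR, OUTCOME):
        if win not in counts:
            counts[win] = 0
    ok = (counts[PREDICTOR] >= min_records) & (counts[OUTCOME] >= min_records)
    return counts.index[ok].to_numpy()


def window_statistics(windowed: pd.DataFrame) -> pd.DataFrame:
    """Summary statistics per (user, window).

    Columns: n_records, n_days, severity_mean, severity_sd, volatility,
    volatility_sd, trend_delta, trend_abs_delta.  Trend columns are NaN for
    groups without two distinct record days.
    """
    rows = []
    for (uid, win), grp in windowed.groupby(["user_id", "window"], sort=True):
        sev = grp["severity"].to_numpy(dtype=float)
        day = grp["day"].to_numpy(dtype=float)
        if day.max() > day.min():
            delta, abs_delta = trend_delta(day, sev)
        else:
            delta, abs_delta = np.nan, np.nan
        rows.append({
            "user_id": uid, "window": win,
            "n_records": len(grp),
            "n_days": int(grp["day"].nunique()),
            "severity_mean": float(sev.mean()),
            "severity_sd": float(np.std(sev, ddof=1)) if len(sev) > 1 else 0.0,
            "volatility": compute_volatility(sev) if len(sev) > 1 else np.nan,
            "volatility_sd": volatility_sd(sev) if len(sev) > 1 else np.nan,
            "trend_delta": delta, "trend_abs_delta": abs_delta,
        })
    return pd.DataFrame(rows).set_index(["user_id", "window"])


def _token_presence(user_records: pd.DataFrame) -> dict[tuple[str, str], bool]:
    present: dict[tuple[str, str], bool] = {}
    for fld, (_, vocab) in sc.RECORD_FIELDS.items():
        vocab_set = set(vocab)
        seen: set[str] = set()
        for cell in user_records[fld]:
            if cell:
                seen.update(cell.split(";"))
        unknown = seen - vocab_set
        if unknown:
            log.warning("dropping unknown %s tokens: %s", fld, sorted(unknown))
        for tok in vocab:
            present[(fld, tok)] = tok in seen
    return present


def extract_features(profile, user_records: pd.DataFrame, window: str,
                     schema: sc.FeatureSchema, volatility_threshold: float,
                     severity_threshold: float,
                     age_default: float | None = None) -> pd.Series:
    """Build one user's feature vector from their records in ``window``.

    ``profile`` is the user's profile row (mapping-like).  Descriptor, factor,
    condition, medication and mental-health features are binary presence
    indicators (reported in >=1 record of the window, or present in the
    profile).  Unknown descriptor tokens are logged and dropped.
    """
    if profile is None:
        raise ConfigurationError("missing profile for user")
    recs = user_records[user_records["window"] == window] \
        if "window" in user_records else user_records
    sev = recs["severity"].to_numpy(dtype=float)
    day = recs["day"].to_numpy(dtype=float)
    vol = compute_volatility(sev)
    vol_sd = volatility_sd(sev)
    if day.max() > day.min():
        delta, abs_delta = trend_delta(day, sev)
    else:
        delta, abs_delta = 0.0, 0.0
    stats = {
        "n_records": float(len(recs)),
        "n_days": float(len(np.unique(day))),
        "severity_mean": float(sev.mean()),
        "severity_sd": float(np.std(sev, ddof=1)) if sev.size > 1 else 0.0,
        "volatility_mean": vol, "volatility_sd": vol_sd,
        "trend_delta": delta, "trend_abs_delta": abs_delta,
        "severity_level": float(sev.mean() >= severity_threshold),
        "volatility_level": float(vol >= volatility_threshold),
    }
    gender = profile.get("gender", "") or "unknown"
    age = profile.get("age", None)
    if age is None or pd.isna(age):
        age = np.nan if age_default is None else float(age_default)
    present = _token_presence(recs)
    prof_tokens = {
        fld: set(str(profile.get(fld, "") or "").split(";")) - {""}
        for fld in ("conditions", "medications")
    }
    values = []
    for f in schema.features:
        if f.name == "gender":
            values.append(float(sc.GENDER_CODES.get(gender,
                                                    sc.GENDER_CODES["unknown"])))
        elif f.name == "age":
            values.append(float(age))
        elif f.name in stats:
            values.append(stats[f.name])
        elif f.field in sc.RECORD_FIELDS:
            values.append(float(present[(f.field, f.token)]))
        else:  # profile set-valued fields (conditions incl. mental health,
            values.append(float(f.token in prof_tokens[f.field]))
    return pd.Series(values, index=schema.names, name=profile["user_id"])


@dataclass
class FeatureExtraction:
    """Cohort-level extraction result."""

    X: pd.DataFrame                  # users x 132, indexed by user_id
    y: pd.Series                     # outcome-window volatility class
    stats: pd.DataFrame              # per (user, window) summary statistics
    labeling: VolatilityLabeling     # pooled k-means labeling (both windows)
    severity_threshold: float
    min_records: int


def build_feature_matrix(profiles: pd.DataFrame, records: pd.DataFrame,
                         schema: sc.FeatureSchema | None = None,
                         min_records: int = 5, seed: int = 0,
                         n_init: int = 25) -> FeatureExtraction:
    """Run the full extraction: windows, filter, thresholds, 132 features.

    The volatility threshold comes from 2-means on the pooled predictor- and
    outcome-window volatility values of eligible users (one threshold for
    both windows); the severity-level threshold is obtained the same way from
    the pooled window mean severities.  Missing ages are imputed with the
    median age of eligible users.
    """
    schema = schema or sc.build_schema()
    windowed = assign_windows(records)
    eligible = filter_users(windowed, min_records=min_records)
    if len(eligible) == 0:
        raise ConfigurationError("no users pass the record-count filter")
    windowed = windowed[windowed["user_id"].isin(eligible)]
    stats = window_statistics(windowed)

    pooled_vol = stats["volatility"].to_numpy(dtype=float)
    labeling = kmeans_threshold(pooled_vol, seed=seed, n_init=n_init)
    sev_threshold = kmeans_threshold(
        stats["severity_mean"].to_numpy(dtype=float),
        seed=seed, n_init=n_init).threshold

    prof = profiles.set_index("user_id", drop=False)
    ages = prof.loc[prof.index.intersection(eligible), "age"]
    age_default = float(ages.dropna().median()) if ages.notna().any() else 45.0

    rows = []
    for uid, grp in windowed[windowed["window"] == PREDICTOR].groupby(
            "user_id", sort=True):
        if uid not in prof.index:
            raise ConfigurationError(f"missing profile for user {uid}")
        rows.append(extract_features(
            prof.loc[uid], grp, PREDICTOR, schema,
            volatility_threshold=labeling.threshold,
            severity_threshold=sev_threshold, age_default=age_default))
    X = pd.DataFrame(rows)
    X.index.name = "user_id"

    out_vol = stats.xs(OUTCOME, level="window").loc[X.index, "volatility"]
    y = pd.Series(np.where(out_vol.to_numpy() >= labeling.threshold,
                           "high", "low"), index=X.index, name="outcome_class")
    return FeatureExtraction(X=X, y=y, stats=stats, labeling=labeling,
                             severity_threshold=sev_threshold,
                             min_records=min_records)
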