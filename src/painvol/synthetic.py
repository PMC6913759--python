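"""Seeded synthetic pain-diary cohorts.

A generated cohort emulates the structure the analysis assumes: each user has
two 30-day observation windows (the predictor window starting at their first
record and an outcome window beginning 150 days later), a planted low/high
volatility class per window, severity series whose mean absolute consecutive
change is controlled per class, and record-level descriptor fields of which a
configurable subset is class-informative.  Cohorts round-trip through the
two-file delimited export (``profiles.csv`` / ``records.csv``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema as sc
from .errors import CohortParseError, CohortValidationError, ConfigurationError

PREDICTOR_OFFSET = 0
OUTCOME_OFFSET = 150
WINDOW_DAYS = 30

#: baseline per-record occurrence probability of any descriptor token
BASE_DESCRIPTOR_RATE = 0.10
#: per-user probability of carrying a condition / medication token
PROFILE_TOKEN_RATE = 0.25
MENTAL_HEALTH_RATE = 0.20
AGE_MISSING_RATE = 0.05
GENDER_MISSING_RATE = 0.02

RECORD_COLUMNS = ["user_id", "date", "severity"] + list(sc.RECORD_FIELDS)
PROFILE_COLUMNS = ["user_id", "age", "gender", "conditions", "medications"]


@dataclass(frozen=True)
class SimParams:
    """Cohort generation parameters.

    Defaults mirror the population the pipeline targets: 879 users of whom
    roughly one in five is high-volatility, continuous 0-10 severities, and
    per-class step scales that put the class boundary of the volatility
    statistic near 1.6.
    """

    n_users: int = 879
    prop_high: float = 185 / 879
    base_severity_mean: float = 5.0
    base_severity_sd: float = 1.5
    step_scale_low: float = 0.8
    step_scale_high: float = 2.8
    class_persistence: float = 0.8
    records_per_window_mean: float = 20.0
    min_records: int = 5
    n_informative_descriptors: int = 9
    descriptor_effect: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.n_users >= 1, "n_users must be >= 1"),
            (0.0 < self.prop_high < 1.0, "prop_high must be in (0,1)"),
            (0.0 <= self.class_persistence <= 1.0,
             "class_persistence must be in [0,1]"),
            (self.step_scale_low >= 0.0, "step_scale_low must be >= 0"),
            (self.step_scale_high > self.step_scale_low,
             "step_scale_high must exceed step_scale_low"),
            (self.records_per_window_mean > 0,
             "records_per_window_mean must be > 0"),
            (self.min_records >= 2, "min_records must be >= 2"),
            (0 <= self.n_informative_descriptors, "n_informative >= 0"),
            (0.0 <= self.descriptor_effect <= 1.0,
             "descriptor_effect must be in [0,1]"),
            (0.0 <= self.base_severity_mean <= 10.0,
             "base_severity_mean must be on the 0-10 scale"),
            (self.base_severity_sd >= 0, "base_severity_sd must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)
        for name in ("prop_high", "base_severity_mean", "base_severity_sd",
                     "step_scale_low", "step_scale_high", "class_persistence",
                     "records_per_window_mean", "descriptor_effect"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=seed)


@dataclass
class Cohort:
    profiles: pd.DataFrame
    records: pd.DataFrame
    truth: pd.DataFrame | None = None
    informative_features: tuple[str, ...] = field(default_factory=tuple)
    params: SimParams | None = None


def _informative_tokens(k: int) -> list[tuple[str, str]]:
    """First ``k`` record-level (field, token) pairs deemed class-informative.

    Chosen deterministically from the symptom/characteristic/factor
    vocabularies so planted cohorts are comparable across seeds.
    """
    pool: list[tuple[str, str]] = []
    for fld in ("symptoms", "characteristics", "aggravating", "alleviating",
                "ineffective", "environments", "location"):
        _, vocab = sc.RECORD_FIELDS[fld]
        pool += [(fld, tok) for tok in vocab]
    if k > len(pool):
        raise ConfigurationError("n_informative_descriptors too large")
    return pool[:k]


def _severity_walk(rng: np.random.Generator, n: int, start_mean: float,
                   start_sd: float, step_scale: float) -> np.ndarray:
    """Bounded Gaussian random walk on the 0-10 scale.

    Step SD is step_scale * sqrt(pi/2) so that, absent boundary clipping,
    E|s_i - s_{i-1}| equals ``step_scale`` (mean absolute value of a centred
    normal is sd * sqrt(2/pi)).
    """
    out = np.empty(n)
    out[0] = min(10.0, max(0.0, rng.normal(start_mean, start_sd)))
    if step_scale == 0.0:
        out[1:] = out[0]
        return out
    sd = step_scale * math.sqrt(math.pi / 2.0)
    steps = rng.normal(0.0, sd, size=n - 1)
    for i in range(1, n):
        out[i] = min(10.0, max(0.0, out[i - 1] + steps[i - 1]))
    return out


def generate_cohort(params: SimParams) -> Cohort:
    """Generate a seeded cohort of user profiles, pain records and truth.

    Returns a :class:`Cohort` whose ``truth`` table holds the planted
    predictor- and outcome-window volatility classes per user.  Identical
    ``params`` (including the seed) reproduce the cohort exactly.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.n_users
    ids = [f"u{i:05d}" for i in range(1, n + 1)]

    pred_high = rng.random(n) < params.prop_high
    keep = rng.random(n) < params.class_persistence
    out_high = np.where(keep, pred_high, ~pred_high)

    informative = _informative_tokens(params.n_informative_descriptors)
    informative_names = tuple(
        f"{sc.RECORD_FIELDS[fld][0]}:{tok}" for fld, tok in informative)

    profiles = _make_profiles(rng, ids)
    rec_rows: list[tuple] = []
    start_offsets = rng.integers(0, 365, size=n)
    base_day = date(2018, 1, 1)
    scale = {False: params.step_scale_low, True: params.step_scale_high}

    for u in range(n):
        start = base_day + timedelta(days=int(start_offsets[u]))
        for win_offset, high in ((PREDICTOR_OFFSET, pred_high[u]),
                                 (OUTCOME_OFFSET, out_high[u])):
            n_rec = int(max(params.min_records,
                            rng.poisson(params.records_per_window_mean)))
            n_rec = min(n_rec, WINDOW_DAYS)
            if win_offset == PREDICTOR_OFFSET:
                # the first record anchors the predictor window at day 0
                days = np.sort(np.concatenate(
                    [[0], rng.choice(np.arange(1, WINDOW_DAYS),
                                     size=n_rec - 1, replace=False)]))
            else:
                days = np.sort(rng.choice(WINDOW_DAYS, size=n_rec,
                                          replace=False))
            sev = _severity_walk(rng, n_rec, params.base_severity_mean,
                                 params.base_severity_sd, scale[bool(high)])
            desc = _descriptor_strings(rng, n_rec, bool(high), informative,
                                       params.descriptor_effect)
            for j in range(n_rec):
                d = start + timedelta(days=int(win_offset + days[j]))
                rec_rows.append((ids[u], d, float(sev[j]),
                                 *[desc[fld][j] for fld in sc.RECORD_FIELDS]))

    records = pd.DataFrame(rec_rows, columns=RECORD_COLUMNS)
    label = np.array(["low", "high"])
    truth = pd.DataFrame({
        "user_id": ids,
        "predictor_class": label[pred_high.astype(int)],
        "outcome_class": label[out_high.astype(int)],
    })
    return Cohort(profiles=profiles, records=records, truth=truth,
                  informative_features=informative_names, params=params)


def _make_profiles(rng: np.random.Generator, ids: list[str]) -> pd.DataFrame:
    n = len(ids)
    ages = np.clip(np.round(rng.normal(47, 16, size=n)), 18, 90).astype(int)
    age_col = pd.array(ages, dtype="Int64")
    age_col[rng.random(n) < AGE_MISSING_RATE] = pd.NA
    gender = rng.choice(["female", "male", "other"], size=n,
                        p=[0.58, 0.39, 0.03]).astype(object)
    gender[rng.random(n) < GENDER_MISSING_RATE] = ""
    conds, meds = [], []
    for _ in range(n):
        tok = [c for c in sc.CONDITIONS if rng.random() < PROFILE_TOKEN_RATE]
        tok += [c for c in sc.MENTAL_HEALTH if rng.random() < MENTAL_HEALTH_RATE]
        conds.append(";".join(tok))
        meds.append(";".join(m for m in sc.MEDICATIONS
                             if rng.random() < PROFILE_TOKEN_RATE))
    return pd.DataFrame({"user_id": ids, "age": age_col, "gender": gender,
                         "conditions": conds, "medications": meds})


def _descriptor_strings(rng, n_rec, high, informative, effect):
    """';'-joined descriptor tokens per record, with class-shifted rates."""
    info = set(informative)
    out: dict[str, list[str]] = {}
    for fld, (_, vocab) in sc.RECORD_FIELDS.items():
        p = np.full(len(vocab), BASE_DESCRIPTOR_RATE)
        for k, tok in enumerate(vocab):
            if (fld, tok) in info and high:
                p[k] = min(1.0, BASE_DESCRIPTOR_RATE + effect)
        draws = rng.random((n_rec, len(vocab))) < p
        out[fld] = [";".join(tok for tok, on in zip(vocab, row) if on)
                    for row in draws]
    return out


# ---------------------------------------------------------------------------
# two-file delimited export

def write_cohort(cohort: Cohort, path: str | Path) -> tuple[Path, Path]:
    """Write ``profiles.csv`` and ``records.csv`` under ``path``.

    Comma-delimited UTF-8 with a header row; set-valued fields are ';'-joined
    tokens; dates are ISO ``YYYY-MM-DD``.  The planted truth, when present,
    is written alongside as ``truth.csv`` (not part of the two-file contract).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ppath, rpath = path / "profiles.csv", path / "records.csv"
    cohort.profiles.to_csv(ppath, index=False)
    rec = cohort.records.copy()
    rec["date"] = rec["date"].astype(str)
    rec.to_csv(rpath, index=False)
    if cohort.truth is not None:
        cohort.truth.to_csv(path / "truth.csv", index=False)
    return ppath, rpath


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Raises :class:`CohortParseError` (naming the offending line) for rows
    missing a mandatory field and :class:`CohortValidationError` for
    out-of-range severities.
    """
    path = Path(path)
    profiles = pd.read_csv(path / "profiles.csv", dtype={"user_id": str},
                           keep_default_na=False, na_values=[])
    profiles["age"] = pd.to_numeric(profiles["age"].replace("", pd.NA),
                                    errors="raise").astype("Int64")
    records = pd.read_csv(path / "records.csv", dtype={"user_id": str},
                          keep_default_na=False, na_values=[])
    if len(records):
        for col in ("user_id", "date", "severity"):
            bad = records[col].astype(str).str.strip() == ""
            if bad.any():
                # +2: header line plus 1-based indexing
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise CohortParseError(
                    f"records.csv line {line}: missing {col}")
        records["severity"] = pd.to_numeric(records["severity"])
        out_of_range = ~records["severity"].between(0.0, 10.0)
        if out_of_range.any():
            line = int(np.flatnonzero(out_of_range.to_numpy())[0]) + 2
            raise CohortValidationError(
                f"records.csv line {line}: severity outside [0,10]")
        records["date"] = pd.to_datetime(records["date"]).dt.date
    else:
        records = pd.DataFrame(columns=RECORD_COLUMNS)
        records["severity"] = records["severity"].astype(float)
    truth_path = path / "truth.csv"
    truth = pd.read_csv(truth_path, dtype=str) if truth_path.exists() else None
    return Cohort(profiles=profiles, records=records, truth=truth)
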