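"""The 132-feature schema describing one user's predictor window.

Features fall into eight categories: demographics (2), app usage (2), pain
statistics (8), pain descriptors (64), factors impacting pain (43), pain
conditions (6), medications (5) and mental-health conditions (2).  Descriptor,
factor, condition, medication and mental-health features are binary presence
indicators; pain statistics are summary numbers of the severity time series,
including the volatility statistic (mean absolute consecutive change) and the
two dichotomised "level" features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

NUMERIC = "numeric"
BINARY = "binary"
CATEGORICAL = "categorical-encoded"

# Record-level descriptor vocabularies (one field per group in the diary file).
LOCATIONS = (
    "head", "jaw", "neck", "shoulder_left", "shoulder_right", "upper_back",
    "lower_back", "chest", "abdomen", "pelvis", "hip_left", "hip_right",
    "elbow_left", "elbow_right", "wrist_left", "wrist_right", "hand_left",
    "hand_right", "knee_left", "knee_right", "ankle_left", "ankle_right",
    "foot_left", "foot_right",
)
SYMPTOMS = (
    "fatigue", "nausea", "dizziness", "insomnia", "stiffness", "swelling",
    "numbness", "tingling", "weakness", "spasm", "cramping", "itching",
    "sweating", "light_sensitivity", "sound_sensitivity", "appetite_loss",
    "irritability", "brain_fog", "restlessness", "headache",
)
CHARACTERISTICS = (
    "aching", "burning", "sharp", "dull", "throbbing", "stabbing", "shooting",
    "tender", "gnawing", "pressure", "pulsing", "radiating", "electric",
)
ENVIRONMENTS = ("home", "work", "outdoors", "commuting", "school",
                "social_event", "bed")
AGGRAVATING = (
    "sitting", "standing", "walking", "lifting", "bending", "stress",
    "cold_weather", "humidity", "exercise", "driving", "stairs", "typing",
    "sleep_deprivation", "noise", "bright_light",
)
ALLEVIATING = (
    "rest", "heat", "ice", "stretching", "massage", "meditation",
    "medication_use", "sleep", "gentle_walking", "distraction", "bath",
    "physiotherapy", "breathing_exercise", "music",
)
INEFFECTIVE = (
    "rest", "heat", "ice", "stretching", "massage", "otc_painkillers",
    "sleep", "distraction", "bath", "physiotherapy", "acupuncture",
    "chiropractic", "yoga", "topical_cream",
)

# Profile-level vocabularies.
CONDITIONS = ("chronic_back_pain", "fibromyalgia", "arthritis", "migraine",
              "neuropathy", "endometriosis")
MEDICATIONS = ("nsaid", "opioid", "acetaminophen", "antidepressant",
               "anticonvulsant")
MENTAL_HEALTH = ("depression", "anxiety")

#: diary-file descriptor fields -> (feature-name prefix, vocabulary)
RECORD_FIELDS: Mapping[str, tuple[str, tuple[str, ...]]] = {
    "location": ("location", LOCATIONS),
    "symptoms": ("symptom", SYMPTOMS),
    "characteristics": ("characteristic", CHARACTERISTICS),
    "environments": ("environment", ENVIRONMENTS),
    "aggravating": ("aggravating", AGGRAVATING),
    "alleviating": ("alleviating", ALLEVIATING),
    "ineffective": ("ineffective", INEFFECTIVE),
}

#: profile set-valued fields -> list of (feature prefix, vocabulary, category)
PROFILE_FIELDS: Mapping[str, tuple[str, tuple[str, ...], str]] = {
    "conditions": ("condition", CONDITIONS, "conditions"),
    "medications": ("medication", MEDICATIONS, "medications"),
}

PAIN_STATISTICS = (
    "severity_mean", "severity_sd", "volatility_mean", "volatility_sd",
    "trend_delta", "trend_abs_delta", "severity_level", "volatility_level",
)

CATEGORY_SIZES = {
    "demographic": 2,
    "app_usage": 2,
    "pain_statistics": 8,
    "pain_descriptors": 64,
    "factors": 43,
    "conditions": 6,
    "medications": 5,
    "mental_health": 2,
}

GENDER_CODES = {"female": 0, "male": 1, "other": 2, "unknown": 3}


@dataclass(frozen=True)
class Feature:
    name: str
    category: str
    kind: str
    #: diary/profile field the feature is read from ("" for computed features)
    field: str = ""
    #: vocabulary token for presence features ("" otherwise)
    token: str = ""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of the 132 features."""

    features: tuple[Feature, ...]

    def __post_init__(self):
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.category] = counts.get(f.category, 0) + 1
        if counts != CATEGORY_SIZES:
            raise ValueError(f"category sizes {counts} != {CATEGORY_SIZES}")
        if len({f.name for f in self.features}) != len(self.features):
            raise ValueError("duplicate feature names")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def by_category(self, category: str) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if f.category == category)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_dict(self) -> list[dict]:
        return [
            {"name": f.name, "category": f.category, "kind": f.kind,
             "field": f.field, "token": f.token}
            for f in self.features
        ]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _presence(prefix: str, vocab: Iterable[str], category: str,
              field: str) -> list[Feature]:
    return [Feature(f"{prefix}:{tok}", category, BINARY, field, tok)
            for tok in vocab]


def build_schema() -> FeatureSchema:
    """Construct the canonical 132-feature schema."""
    feats: list[Feature] = [
        Feature("gender", "demographic", CATEGORICAL, "gender"),
        Feature("age", "demographic", NUMERIC, "age"),
        Feature("n_records", "app_usage", NUMERIC),
        Feature("n_days", "app_usage", NUMERIC),
    ]
    for name in PAIN_STATISTICS:
        kind = BINARY if name.endswith("_level") else NUMERIC
        feats.append(Feature(name, "pain_statistics", kind))
    for field in ("location", "symptoms", "characteristics", "environments"):
        prefix, vocab = RECORD_FIELDS[field]
        feats += _presence(prefix, vocab, "pain_descriptors", field)
    for field in ("aggravating", "alleviating", "ineffective"):
        prefix, vocab = RECORD_FIELDS[field]
        feats += _presence(prefix, vocab, "factors", field)
    feats += _presence("condition", CONDITIONS, "conditions", "conditions")
    feats += _presence("medication", MEDICATIONS, "medications", "medications")
    feats += _presence("mental_health", MENTAL_HEALTH, "mental_health",
                       "conditions")
    return FeatureSchema(tuple(feats))


#: names of the record-stream features a planted volatility class drives
VOLATILITY_STATISTIC_FEATURES = ("volatility_mean", "volatility_sd",
                                 "volatility_level")
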