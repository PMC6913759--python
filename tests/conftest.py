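import numpy as np
import pandas as pd
import pytest

import painvol as pv


@pytest.fixture(scope="session")
def small_cohort():
    """120 users, enough signal for shape/round-trip tests."""
    return pv.generate_cohort(pv.SimParams(n_users=120, seed=42))


@pytest.fixture(scope="session")
def small_extraction(small_cohort):
    return pv.build_feature_matrix(small_cohort.profiles,
                                   small_cohort.records, seed=42)


@pytest.fixture(scope="session")
def labeled_frame():
    """A simple separable feature frame with string labels."""
    rng = np.random.default_rng(7)
    n = 240
    y = pd.Series(np.where(rng.random(n) < 0.5, "high", "low"),
                  index=[f"u{i:03d}" for i in range(n)])
    X = pd.DataFrame(rng.normal(size=(n, 12)),
                     columns=[f"f{i}" for i in range(12)], index=y.index)
    X["f0"] += np.where(y == "high", 2.0, 0.0)
    return X, y
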