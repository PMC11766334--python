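import numpy as np
import pandas as pd
import pytest

from mixrfb import CohortSpec, MixRFbConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Complete (no missingness) cohort at the default study conditions."""
    return generate_cohort(CohortSpec(missing_rate={}, seed=0))


@pytest.fixture(scope="session")
def fast_config():
    return MixRFbConfig(n_trees=60, seed=3)


def make_threshold_frame(n_rows=300, threshold=15.0, seed=0, noise_feature=True):
    """Toy single-day cohort whose outcome is exactly indicator(rdw > threshold)."""
    rng = np.random.default_rng(seed)
    rdw = rng.uniform(11.0, 19.0, n_rows)
    df = pd.DataFrame({
        "patient_id": [f"T{i:04d}" for i in range(n_rows)],
        "day": 1,
        "rdw": rdw,
        "outcome": np.where(rdw > threshold, "death", "survival"),
    })
    if noise_feature:
        df["age"] = rng.uniform(20.0, 90.0, n_rows)
    return df


@pytest.fixture
def threshold_frame():
    return make_threshold_frame()
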