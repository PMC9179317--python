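import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import calspline as cs

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """Two small local-lab studies; quick to generate and fit."""
    return cs.default_scenario(
        n_studies=2,
        pairs_per_study=60,
        a=(-1.0, 1.5),
        b=(0.8, 1.25),
        sigma2_w=(1.2, 0.6),
        calibration_proportion=0.3,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return cs.generate_pooled_data(small_config, seed=101)


def to_reference_lab(dataset_with_latent: cs.PooledDataset) -> cs.PooledDataset:
    """Reveal the latent reference-scale value for every subject."""
    df = dataset_with_latent.table.copy()
    df["reference_value"] = df["latent_x"]
    df["in_calibration"] = False
    df = df.drop(columns="latent_x")
    return cs.PooledDataset.from_frame(df)


@pytest.fixture(scope="session")
def reference_dataset(small_config):
    """All-reference-laboratory pooled dataset (no calibration needed)."""
    data = cs.generate_pooled_data(small_config, seed=202, include_latent=True)
    return to_reference_lab(data)


def random_nm_strata(rng, n_strata=8, max_total=6, dim=2):
    """Random mixed n:m matched sets as a pooled frame (reference lab)."""
    rows = []
    for j in range(n_strata):
        total = rng.integers(2, max_total + 1)
        n_cases = rng.integers(1, total)
        y = np.r_[np.zeros(total - n_cases, dtype=int), np.ones(n_cases, dtype=int)]
        x = rng.normal(size=total)
        for yi, xi in zip(y, x):
            rows.append(
                {
                    "study": "s1",
                    "stratum": j,
                    "case": yi,
                    "local_value": xi,
                    "reference_value": xi,
                    "in_calibration": 0,
                }
            )
    return cs.PooledDataset.from_frame(pd.DataFrame(rows))
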