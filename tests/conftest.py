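"""Shared fixtures: small simulated datasets and random survival data."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from survcut import Scenario, SurvivalDataset, simulate_dataset


@pytest.fixture(scope="session")
def weibull_scenario() -> Scenario:
    return Scenario("weibull", theta=0.2, n_obs=250, pc_t=0.2, pc_f=0.25, seed=42)


@pytest.fixture(scope="session")
def weibull_data(weibull_scenario) -> SurvivalDataset:
    return simulate_dataset(weibull_scenario, seed=1)


def random_survival_data(rng: np.random.Generator, n: int, n_covariates: int = 0,
                         with_ties: bool = False) -> SurvivalDataset:
    """Random dataset with no built-in biomarker effect."""
    time = rng.exponential(1.0, n)
    if with_ties:
        time = np.round(time, 1) + 0.05
    event = rng.integers(0, 2, n)
    if event.sum() == 0:
        event[rng.integers(0, n)] = 1
    frame = pd.DataFrame({"time": time, "event": event,
                          "X": rng.standard_normal(n)})
    cols = []
    for j in range(n_covariates):
        frame[f"Z{j + 1}"] = rng.standard_normal(n)
        cols.append(f"Z{j + 1}")
    return SurvivalDataset(frame, covariate_cols=tuple(cols))
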