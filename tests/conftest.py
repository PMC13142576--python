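import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from iivd.pipeline import RunConfig, run_full_pipeline
from iivd.registry import default_registry
from iivd.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def default_cohort():
    """One published-scale simulated cohort (102 HC + 832 Stage 2, two visits)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_bundle():
    """Full pipeline bundle at the default configuration."""
    return run_full_pipeline(RunConfig(seed=11))


@pytest.fixture()
def tiny_cohort(default_cohort):
    """Small cohort slice (first 30 participants) for IO round-trips."""
    ids = default_cohort["participant_id"].unique()[:30]
    return default_cohort[default_cohort["participant_id"].isin(ids)].reset_index(
        drop=True
    )


def random_panel_frame(rng: np.random.Generator, n: int, registry) -> pd.DataFrame:
    """Random complete T-score panel table for oracle comparisons."""
    data = {
        "participant_id": [f"P{i}" for i in range(n)],
        "visit_index": 0,
    }
    for name in registry.names:
        data[name] = 50 + 10 * rng.standard_normal(n)
    return pd.DataFrame(data)
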