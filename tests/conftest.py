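import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from nutrinet import SimulationConfig, simulate_grn, simulate_multistudy

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Down-scaled study design used by most integration-style tests."""
    return SimulationConfig(
        n_genes=400,
        studies_per_stress=2,
        n_mutant_specific={"gpa1": 40, "agb1": 30},
        planted_intersection={"gpa1": 5, "agb1": 8},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_multistudy(small_config)


@pytest.fixture(scope="session")
def small_grn():
    config = SimulationConfig(n_tfs=8, targets_per_tf=4, grn_samples=40, seed=5)
    return simulate_grn(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_matrix():
    return pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 6.0, 8.0]},
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
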