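import numpy as np
import pandas as pd
import pytest

from habitatlink import simulate
from habitatlink.otu import OtuTable


@pytest.fixture(scope="session")
def small_config():
    """Reduced problem sizes for fast end-to-end runs."""
    return simulate.SimulationConfig(
        n_gardens=8,
        markers={"16S": simulate.MarkerConfig(depth=300, richness=60)},
        n_real_features=5,
        n_artifact_features=12,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate.simulate_study(small_config, seed=11)


@pytest.fixture(scope="session")
def default_study():
    """One study at the survey's own shape (23 gardens, 3 markers)."""
    return simulate.simulate_study(seed=7)


@pytest.fixture
def toy_table():
    """Hand-sized OTU table with one negative control."""
    counts = pd.DataFrame(
        {
            "S1_NC": [60, 0, 20, 10, 10],
            "S1_C": [20, 20, 0, 30, 30],
            "S2_NC": [30, 10, 10, 25, 25],
            "NEG1": [0, 0, 5, 0, 0],
        },
        index=[f"OTU{i}" for i in range(1, 6)],
    )
    meta = pd.DataFrame(
        {
            "garden_id": ["S1", "S1", "S2", "none"],
            "sample_type": ["NC", "C", "NC", "NEG"],
            "marker": ["16S"] * 4,
        },
        index=counts.columns,
    )
    return OtuTable(counts, sample_meta=meta)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
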