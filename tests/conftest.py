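import numpy as np
import pytest

from drowsebold.io import default_atlas
from drowsebold.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_atlas():
    return default_atlas(14)


@pytest.fixture(scope="session")
def small_dataset(small_atlas):
    """Shared 8-participant, 15-minute cohort (with default injected effects)."""
    cfg = SimulationConfig(n_participants=8, duration_s=900.0, fps=10.0, seed=7)
    return simulate_dataset(cfg, atlas=small_atlas)


@pytest.fixture(scope="session")
def small_psd_table(small_dataset):
    from drowsebold.pipeline import cohort_state_psd_table

    table, drowsigrams = cohort_state_psd_table(small_dataset)
    return table, drowsigrams


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
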