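import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured cohort shared across test modules."""
    from striaparc.synth import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(
        seed=11,
        n_nodes=40,
        n_networks=5,
        n_striatal_voxels=60,
        n_timepoints=150,
        n_patients=12,
        n_controls=8,
    )
    return generate_dataset(cfg)
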