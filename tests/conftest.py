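import numpy as np
import pytest

import neurofuse as nf
from neurofuse.model import ModelConfig
from neurofuse.train_eval import TrainConfig


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 sites x (4 MDD + 4 HC), 8 regions, 10x12x10 volumes."""
    cfg = nf.SimulationConfig(
        n_sites=3, subjects_per_site=(4, 4), d_regions=8,
        t_ranges=[(90, 94), (95, 99), (100, 104)], gmv_dims=(10, 12, 10),
        seed=7)
    cohort, truth = nf.simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig.compact(d_in=8, n_sites=3)


@pytest.fixture(scope="session")
def tiny_train_config():
    return TrainConfig.desk_scale(epochs=2, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
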