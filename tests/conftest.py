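import numpy as np
import pytest

from ednamix.experiments import RunConfig, prepare_study
from ednamix.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A reduced study: fewer loci and shallower reads, same structure."""
    return SimulationConfig(
        n_loci=8,
        tissue_depth=6000,
        edna_depth=5000,
        field_depth=1500,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    truth = simulate_study(small_cfg, np.random.default_rng(small_cfg.seed))
    cfg = RunConfig(sim=small_cfg, seed=small_cfg.seed, n_bootstrap=20)
    return prepare_study(truth, cfg), cfg
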