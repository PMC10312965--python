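import numpy as np
import pytest

from mesostate import MazeGeometry, SyntheticConfig
from mesostate.synthetic import make_templates, simulate_cohort


@pytest.fixture(scope="session")
def geom() -> MazeGeometry:
    return MazeGeometry.standard()


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-size cohort used by the slower integration tests."""
    return SyntheticConfig(n_mice=2, trials_per_mouse=3, trial_duration_s=20.0,
                           seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def templates7():
    cfg = SyntheticConfig()
    return make_templates(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
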