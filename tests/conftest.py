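import numpy as np
import pytest

from lcquant.core import VolumeGrid
from lcquant.synthetic import SimulationConfig, make_cohort, small_config


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Reduced phantom configuration shared across tests."""
    return small_config()


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, fully materialised cohort (reused read-only)."""
    cfg = small_config()
    cfg.n_per_group = {"HC": 6, "PD": 6, "PSP": 5}
    cfg.seed = 42
    return make_cohort(cfg)


@pytest.fixture()
def identity_grid():
    return VolumeGrid(np.zeros((8, 8, 8)), np.eye(4))


def pooled_sd(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return np.sqrt(
        ((len(a) - 1) * a.std(ddof=1) ** 2 + (len(b) - 1) * b.std(ddof=1) ** 2)
        / (len(a) + len(b) - 2)
    )
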