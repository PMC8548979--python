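"""Shared fixtures: default layout and a small simulated cohort."""

import numpy as np
import pytest

from nirspain.probe import default_layout
from nirspain.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small-session config: full channel count, shortened phases."""
    return SimulationConfig(
        n_per_group=2,
        visits=1,
        rest_pre_s=40.0,
        breathing_s=60.0,
        rest_post_s=20.0,
        n_trials=4,
        seed=20240915,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    """4 recordings (2 groups x 2 subjects x 1 visit) with ground truth."""
    recs, behavior, truth = simulate_cohort(tiny_cfg, keep_true_hbo=True)
    return recs, behavior, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
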