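"""Shared fixtures: seeded synthetic worlds and their pipeline results.

The stochastic desk world is deliberately modest (15×15 grid, 50 species,
3 pseudo-GCMs, one recovery-trend and one cropland-expansion scenario) so
the full 1950–2100 daily-climate pipeline runs in seconds; it is shared
session-wide by every test that only reads from it.
"""

import numpy as np
import pytest

from heatland import (PipelineSettings, WorldConfig, generate_world,
                      make_half_loss_world, make_null_world, run_pipeline)

DESK_SEED = 20259
DESK_SCENARIOS = ("SSP1-RCP2.6", "SSP2-RCP4.5")


@pytest.fixture(scope="session")
def desk_config() -> WorldConfig:
    return WorldConfig(seed=DESK_SEED, n_rows=15, n_cols=15, n_species=50,
                       n_gcms=3, scenarios=DESK_SCENARIOS)


@pytest.fixture(scope="session")
def desk_world(desk_config):
    return generate_world(desk_config)


@pytest.fixture(scope="session")
def desk_result(desk_world):
    return run_pipeline(desk_world)


@pytest.fixture(scope="session")
def null_world(desk_config):
    return make_null_world(desk_config)


@pytest.fixture(scope="session")
def null_result(null_world):
    return run_pipeline(null_world)


@pytest.fixture(scope="session")
def half_loss_world():
    return make_half_loss_world(seed=0)


@pytest.fixture(scope="session")
def half_loss_result(half_loss_world):
    return run_pipeline(half_loss_world)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
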