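"""Shared fixtures: small grids and schedules keep unit tests fast."""

import numpy as np
import pytest
from hypothesis import settings

from nfdecode import (
    ActivationTopography,
    Region,
    SubjectConfig,
    build_schedule,
    simulate_run,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SMALL_GRID = (16, 16, 10)


@pytest.fixture(scope="session")
def default_schedule():
    return build_schedule(9, 4, 4, block_s=30.0, tr_s=2.0)


@pytest.fixture(scope="session")
def small_schedule():
    # 5 rest + 2 LGO + 2 RGO blocks of 20 s at TR 2 s -> 90 volumes
    return build_schedule(5, 2, 2, block_s=20.0, tr_s=2.0)


@pytest.fixture(scope="session")
def small_topography():
    return ActivationTopography(
        regions=(
            Region((11, 8, 5), radius=2.0, amplitude=3.0, selectivity="LGO"),
            Region((5, 8, 5), radius=2.0, amplitude=3.0, selectivity="RGO"),
            Region((8, 12, 5), radius=2.0, amplitude=2.0, selectivity="BOTH",
                   relevance="transient"),
        )
    )


@pytest.fixture(scope="session")
def small_config():
    return SubjectConfig(seed=7, grid_dims=SMALL_GRID, noise_sd=1.0, drift_slope=0.02)


@pytest.fixture(scope="session")
def quiet_config():
    """Near-noiseless variant for separability / ground-truth checks.

    noise_sd stays just above float32 resolution at the baseline level so
    voxel time courses are not exactly constant.
    """
    return SubjectConfig(
        seed=7, grid_dims=SMALL_GRID, noise_sd=1e-3, ar1=0.0, drift_slope=0.0
    )


@pytest.fixture(scope="session")
def small_run(small_schedule, small_topography, small_config):
    return simulate_run(small_schedule, small_topography, small_config, run_index=0)


@pytest.fixture(scope="session")
def quiet_run(small_schedule, small_topography, quiet_config):
    return simulate_run(small_schedule, small_topography, quiet_config, run_index=0)
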