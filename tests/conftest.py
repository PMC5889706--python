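import numpy as np
import pytest

from smrpva.habitat import CoverGrid, StateSpace
from smrpva.smr import MCMCConfig, fit_smr
from smrpva.synthetic import SimConfig, simulate_dataset


@pytest.fixture
def two_cell_space() -> StateSpace:
    """Two equal-area cells with vegetation cover 0 and 1."""
    return StateSpace(
        x=[50.0, 150.0],
        y=[50.0, 50.0],
        area_km2=[0.01, 0.01],
        veg=[0.0, 1.0],
        habitat=[False, True],
        cell_size=100.0,
        row=np.array([0, 0]),
        col=np.array([0, 1]),
        grid_shape=(1, 2),
        grid_origin=(0.0, 0.0),
    )


@pytest.fixture
def uniform_cover() -> CoverGrid:
    """A 60 x 60 fully vegetated cover raster at 50-m pixels."""
    return CoverGrid(np.ones((60, 60)), origin=(-1500.0, -1500.0), pixel_size=50.0)


def small_sim_config(**overrides) -> SimConfig:
    """A scaled-down survey: short transect, small buffer, quick to fit."""
    base = dict(
        seed=11,
        N_true=6,
        n_cameras=10,
        n_occasions=12,
        baiting_occasions=(0, 8),
        trap_nights=8,
        buffer=400.0,
        pixel_size=50.0,
        telemetry_locs_per_individual=40,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_fit():
    """One small end-to-end fit shared by the posterior-shape tests."""
    cfg = SimConfig(
        seed=11,
        N_true=6,
        n_cameras=10,
        n_occasions=12,
        baiting_occasions=(0, 8),
        trap_nights=8,
        buffer=400.0,
        pixel_size=50.0,
        telemetry_locs_per_individual=40,
    )
    data, pop, ss = simulate_dataset(cfg)
    mcmc = MCMCConfig(
        chains=2, iterations=800, burn_in=400, thin=2, M_aug=20, seed=7
    )
    posterior = fit_smr(data, mcmc)
    return data, pop, ss, mcmc, posterior
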