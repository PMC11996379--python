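import numpy as np
import pytest

from tdfret import (
    BufferModel,
    DistanceDistribution,
    DonorModel,
    FretDecayParameters,
    SimulationConfig,
    simulate_decay,
    simulate_irf,
)
from tdfret.fitting import fit_buffer
from tdfret.simulate import DONOR_MODEL, FORSTER_RADIUS_ACD_RU


@pytest.fixture(scope="session")
def donor_model():
    return DONOR_MODEL


@pytest.fixture(scope="session")
def r0():
    return FORSTER_RADIUS_ACD_RU


def make_pair(
    rho1,
    rho2=None,
    f_D=0.05,
    seed=0,
    n_bins=512,
    total_counts=1e6,
    f_B=0.5,
    bkgr_dec=5.0,
    with_buffer=True,
):
    """Small synthetic sample/buffer/IRF triple for fitting unit tests."""
    truth = FretDecayParameters(
        f_D=f_D,
        donor=DONOR_MODEL,
        R0=FORSTER_RADIUS_ACD_RU,
        rho1=rho1,
        rho2=rho2,
        f_B=f_B,
        A0=1.0,
        bkgr_dec=bkgr_dec,
    )
    cfg = SimulationConfig(
        truth=truth,
        buffer=BufferModel(((1.0, 2.0),)) if with_buffer else None,
        n_bins=n_bins,
        total_counts=total_counts,
        seed=seed,
    )
    irf = simulate_irf(cfg)
    pair, truth_eff, buffer_eff = simulate_decay(cfg, irf)
    return pair, truth_eff, buffer_eff


@pytest.fixture(scope="session")
def resting_pair():
    """Single-Gaussian resting-state decay plus its fitted buffer model."""
    pair, truth, _ = make_pair(DistanceDistribution.single(41.7, 2.3), seed=41)
    bmodel, _ = fit_buffer(pair.buffer, pair.irf, 1)
    return pair, truth, bmodel


@pytest.fixture(scope="session")
def mixed_pair():
    """Two-Gaussian decay (f_A2 = 0.6) plus its fitted buffer model."""
    rho1 = DistanceDistribution.two_state(0.6, (41.7, 2.3), (28.8, 2.1))
    pair, truth, _ = make_pair(rho1, seed=42, total_counts=3e6)
    bmodel, _ = fit_buffer(pair.buffer, pair.irf, 1)
    return pair, truth, bmodel
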