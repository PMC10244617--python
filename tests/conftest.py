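"""Shared fixtures: the standard hop-diffusion study conditions.

The expensive ensembles (100 hop trajectories, the 5,000-trajectory RD
null, TILD detection over 25 trajectories per scenario) are built once per
session and shared between the module tests and the acceptance tests.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import spthop as sp

#: the standard study conditions: D_micro = 9 um^2/s, L = 100 nm,
#: p = 0.0005 per attempt, 0.1-us micro-steps, 1,000 frames at 10 kHz
STD = dict(
    d_micro=9.0, L=100.0, p_cross=0.0005, frame_time=1e-4, n_frames=1000,
    micro_step=1e-7,
)
NOISE_SD = 50.0
SEED = 1


@pytest.fixture(scope="session")
def std_config() -> sp.HopSimConfig:
    return sp.HopSimConfig(seed=SEED, loc_error_sd=NOISE_SD, **STD)


@pytest.fixture(scope="session")
def hop_ensemble(std_config) -> list[sp.SimulatedTrajectory]:
    """100 hop trajectories under the standard conditions (clean)."""
    return sp.simulate_hop_ensemble(std_config, 100)


@pytest.fixture(scope="session")
def noisy_hop_trajectories(hop_ensemble) -> list[sp.Trajectory]:
    """The same ensemble with 50-nm per-coordinate localization error."""
    return [
        sp.add_localization_noise(s.trajectory, NOISE_SD, seed=SEED + 1, traj_id=i)
        for i, s in enumerate(hop_ensemble)
    ]


@pytest.fixture(scope="session")
def rd_thresholds() -> sp.RDThresholds:
    """RD(1000, 100) thresholds from 5,000 noise-free Brownian nulls."""
    return sp.rd_null_thresholds(N=1000, n=100, frame_time=1e-4, n_sim=5000,
                                 seed=SEED + 2)


@pytest.fixture(scope="session")
def confined_ensemble() -> list[sp.SimulatedTrajectory]:
    """100 fully confined (p_cross=0) trajectories, 500 frames each."""
    cfg = sp.HopSimConfig(
        d_micro=9.0, L=100.0, p_cross=0.0, frame_time=1e-4, n_frames=500,
        seed=SEED + 3,
    )
    return sp.simulate_hop_ensemble(cfg, 100)


@pytest.fixture(scope="session")
def tild_params() -> sp.TildParams:
    return sp.TildParams(loc_error_sd=NOISE_SD)


@pytest.fixture(scope="session")
def tild_hop_results(hop_ensemble, noisy_hop_trajectories, tild_params):
    """TILD detection on the first 25 noisy hop trajectories."""
    results = [
        sp.detect_tilds(tr, tild_params) for tr in noisy_hop_trajectories[:25]
    ]
    return results, hop_ensemble[:25]


@pytest.fixture(scope="session")
def tild_brownian_results(tild_params):
    """TILD detection on 25 noisy Brownian nulls (D = 6 um^2/s)."""
    out = []
    for i in range(25):
        tr = sp.simulate_brownian_trajectory(6.0, 1000, 1e-4, seed=SEED + 4,
                                             traj_id=i)
        noisy = sp.add_localization_noise(tr, NOISE_SD, seed=SEED + 5, traj_id=i)
        out.append(sp.detect_tilds(noisy, tild_params))
    return out
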