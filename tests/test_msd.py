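"""MSD computation, RD classification, and diffusion-model fits."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spthop as sp
from spthop.msd import confined_msd_model, hop_msd_model
from spthop.units import d_um2s_to_nm2s


def brute_force_msd(x, n, all_pairs):
    """Independent double-loop oracle for the time-averaged 1-D MSD."""
    N = len(x)
    m = (N - n) if all_pairs else (N - 1 - n)
    return sum((x[j + n] - x[j]) ** 2 for j in range(m)) / m


def test_msd_hand_example():
    """1-D positions [0,1,2,3] nm: MSD(1)=1, MSD(2)=4 under the printed
    indexing (the pair ending at the final frame is dropped)."""
    tr = sp.Trajectory(np.column_stack([[0, 1, 2, 3], [0, 0, 0, 0]]), 1.0)
    c = sp.compute_msd(tr, 2)
    assert c.msd_x[0] == pytest.approx(1.0)
    assert c.msd_x[1] == pytest.approx(4.0)
    assert np.all(c.msd_y == 0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    n_frames=st.integers(10, 50),
    seed=st.integers(0, 10_000),
    all_pairs=st.booleans(),
)
def test_msd_equals_brute_force(n_frames, seed, all_pairs):
    rng = np.random.default_rng(seed)
    pos = rng.normal(0, 50, (n_frames, 2))
    tr = sp.Trajectory(pos, 1e-4)
    c = sp.compute_msd(tr, n_frames - 2, all_pairs=all_pairs)
    for i, n in enumerate(range(1, n_frames - 1)):
        np.testing.assert_allclose(c.msd_x[i], brute_force_msd(pos[:, 0], n, all_pairs))
        np.testing.assert_allclose(c.msd_y[i], brute_force_msd(pos[:, 1], n, all_pairs))
        assert c.msd_2d[i] == pytest.approx(c.msd_x[i] + c.msd_y[i])


def test_msd_stationary_and_ballistic():
    tr = sp.Trajectory(np.full((20, 2), 7.0), 1e-3)
    assert np.all(sp.compute_msd(tr, 10).msd_2d == 0)
    v = 5.0  # nm per frame along x
    t = np.arange(30)
    tr = sp.Trajectory(np.column_stack([v * t, np.zeros(30)]), 1.0)
    c = sp.compute_msd(tr, 10)
    np.testing.assert_allclose(c.msd_x, (v * np.arange(1, 11)) ** 2)


def _curve_from_values(lags, values, frame_time):
    values = np.asarray(values, dtype=float)
    return sp.MSDCurve(
        lags=np.asarray(lags, dtype=float), msd_x=values / 2, msd_y=values / 2,
        msd_2d=values, n_pairs=np.full(len(values), 100), frame_time=frame_time,
    )


def test_short_term_fit_exact_line():
    dt = 1e-4
    lags = np.arange(1, 6) * dt
    d_nm = d_um2s_to_nm2s(1.0)
    c = _curve_from_values(lags, 4 * d_nm * lags, dt)
    fit = sp.estimate_short_term(c)
    assert fit.d_2_4 == pytest.approx(1.0)
    assert fit.offset == pytest.approx(0.0, abs=1e-6)
    c2 = _curve_from_values(lags, 4 * d_nm * lags + 4 * 50.0**2, dt)
    fit2 = sp.estimate_short_term(c2)
    assert fit2.offset == pytest.approx(1e4)
    assert fit2.sigma_xy == pytest.approx(50.0)
    assert fit2.d_2_4 == pytest.approx(1.0)


def test_short_term_fit_three_point_closed_form():
    """(0.2 ms, 900), (0.3, 1300), (0.4, 1700) -> slope 4e6 nm^2/s,
    so D_2-4 = 1.0 um^2/s with offset 100 nm^2."""
    dt = 1e-4
    c = _curve_from_values(
        np.array([1, 2, 3, 4]) * dt, [500.0, 900.0, 1300.0, 1700.0], dt
    )
    fit = sp.estimate_short_term(c)
    assert fit.d_2_4 == pytest.approx(1.0)
    assert fit.offset == pytest.approx(100.0)


def test_offset_shift_invariance():
    """Adding a constant c to every MSD value shifts the offset by exactly
    c and leaves D_2-4 unchanged."""
    rng = np.random.default_rng(1)
    dt = 1e-4
    lags = np.arange(1, 8) * dt
    base = 4e6 * lags + rng.normal(0, 20, len(lags))
    f0 = sp.estimate_short_term(_curve_from_values(lags, base, dt))
    f1 = sp.estimate_short_term(_curve_from_values(lags, base + 777.0, dt))
    assert f1.offset - f0.offset == pytest.approx(777.0, abs=1e-6)
    assert f1.d_2_4 == pytest.approx(f0.d_2_4)


def test_rd_brownian_mean_near_one():
    """RD(1000,100) over a Brownian ensemble has mean ~= 1 (3 SE)."""
    vals = []
    for i in range(2000):
        tr = sp.simulate_brownian_trajectory(1.0, 1000, 1e-4, seed=9, traj_id=i)
        vals.append(sp.rd_statistic(tr, 100))
    vals = np.array(vals)
    se = vals.std() / math.sqrt(len(vals))
    assert abs(vals.mean() - 1.0) < 3 * se + 0.01


def test_rd_null_threshold_properties(rd_thresholds):
    thr = rd_thresholds
    assert thr.rd_min < 1.0 < thr.rd_max
    # calibration: ~2.5% of a fresh Brownian batch falls below rd_min
    below = above = 0
    n_fresh = 1500
    for i in range(n_fresh):
        tr = sp.simulate_brownian_trajectory(2.0, 1000, 1e-4, seed=77, traj_id=i)
        rd = sp.rd_statistic(tr, 100)
        below += rd < thr.rd_min
        above += rd > thr.rd_max
    assert abs(below / n_fresh - 0.025) < 0.01
    assert abs(above / n_fresh - 0.025) < 0.01


def test_classify_modes(rd_thresholds, confined_ensemble):
    # fresh Brownian batch: ~95% brownian
    labels = [
        sp.classify_mode(
            sp.simulate_brownian_trajectory(3.0, 1000, 1e-4, seed=78, traj_id=i),
            rd_thresholds,
        )
        for i in range(200)
    ]
    frac_brownian = labels.count("brownian") / len(labels)
    assert frac_brownian > 0.90
    # strong drift: directed
    t = np.arange(1000)
    drift = sp.Trajectory(np.column_stack([50.0 * t, np.zeros(1000)]), 1e-4)
    noisy_drift = sp.add_localization_noise(drift, 20.0, seed=1)
    assert sp.classify_mode(noisy_drift, rd_thresholds) == "directed"
    # fully confined trajectories: suppressed (pad p=0 sims to 1000 frames
    # is not possible; simulate directly)
    cfg = sp.HopSimConfig(d_micro=9, L=100, p_cross=0.0, frame_time=1e-4,
                          n_frames=1000, seed=5)
    sim = sp.simulate_hop_trajectory(cfg)
    assert sp.classify_mode(sim.trajectory, rd_thresholds) == "suppressed"


def test_hop_model_limits():
    """Initial slope 4 D_micro; asymptotic slope 4 D_MACRO; D_MACRO -> 0
    reduces to a pure plateau at L^2/3."""
    d_micro, d_macro, L = 9.0, 0.3, 100.0
    t_small = np.array([1e-9, 2e-9])
    slope0 = np.diff(hop_msd_model(t_small, d_micro, d_macro, L))[0] / 1e-9
    assert slope0 == pytest.approx(4 * d_um2s_to_nm2s(d_micro), rel=1e-3)
    t_large = np.array([10.0, 10.001])
    slope_inf = np.diff(hop_msd_model(t_large, d_micro, d_macro, L))[0] / 0.001
    assert slope_inf == pytest.approx(4 * d_um2s_to_nm2s(d_macro), rel=1e-3)
    almost_confined = hop_msd_model(np.array([1.0]), d_micro, 1e-12, L)[0]
    assert almost_confined == pytest.approx(L * L / 3.0, rel=1e-3)


def test_hop_fit_noise_free_round_trip():
    t = np.arange(1, 251) * 1e-4
    true = (9.0, 0.3, 100.0)
    curve = _curve_from_values(t, hop_msd_model(t, *true), 1e-4)
    fit = sp.fit_hop_diffusion(curve)
    assert fit.converged
    assert fit.d_micro == pytest.approx(true[0], rel=0.01)
    assert fit.d_macro == pytest.approx(true[1], rel=0.01)
    assert fit.L == pytest.approx(true[2], rel=0.01)


def test_hop_fit_on_simulated_ensemble(hop_ensemble):
    """L recovered within 10% of the 100-nm lattice; D_MACRO agrees with
    the ensemble's own ground-truth hop rate within 10%."""
    curves = [sp.compute_msd(s.trajectory, 250) for s in hop_ensemble]
    fit = sp.fit_hop_diffusion(sp.ensemble_msd(curves))
    assert fit.converged
    assert abs(fit.L / 100.0 - 1.0) < 0.10
    # ground-truth macroscopic D from the logged hop rate: D = rate*L^2/4
    total_T = sum(s.trajectory.n_frames - 1 for s in hop_ensemble) * 1e-4
    rate = sum(s.n_hops for s in hop_ensemble) / total_T
    d_macro_truth = rate * (0.1**2) / 4.0  # um^2/s
    assert abs(fit.d_macro / d_macro_truth - 1.0) < 0.10


def test_confined_model_limits_and_fit(confined_ensemble):
    L, d = 100.0, 9.0
    # series plateau and initial slope
    assert confined_msd_model(np.array([1.0]), L, d)[0] == pytest.approx(
        L * L / 3.0, rel=1e-6
    )
    t0 = np.array([1e-9, 2e-9])
    slope = np.diff(confined_msd_model(t0, L, d))[0] / 1e-9
    assert slope == pytest.approx(4 * d_um2s_to_nm2s(d), rel=1e-2)
    # round trip on the model
    t = np.arange(1, 101) * 1e-4
    curve = _curve_from_values(t, confined_msd_model(t, L, d), 1e-4)
    fit = sp.fit_confined_diffusion(curve)
    assert fit.L == pytest.approx(L, rel=0.01)
    assert fit.d_micro == pytest.approx(d, rel=0.02)
    # recovery from the p_cross=0 simulation
    curves = [sp.compute_msd(s.trajectory, 200) for s in confined_ensemble]
    fit2 = sp.fit_confined_diffusion(sp.ensemble_msd(curves))
    assert abs(fit2.L / L - 1.0) < 0.05


def test_anomaly_exponents(confined_ensemble):
    # Brownian: alpha ~= 1
    curves = []
    for i in range(1000):
        tr = sp.simulate_brownian_trajectory(2.0, 120, 1e-4, seed=13, traj_id=i)
        curves.append(sp.compute_msd(tr, 60))
    ens = sp.ensemble_msd(curves)
    a = sp.anomaly_curve([ens])
    assert abs(a.alpha - 1.0) < 0.05
    # fully confined, long lags: MSD constant so alpha ~= 0
    cc = [sp.compute_msd(s.trajectory, 400) for s in confined_ensemble]
    ens_c = sp.ensemble_msd(cc)
    a_c = sp.anomaly_curve([ens_c], fit_window=(20e-3, 40e-3))
    assert abs(a_c.alpha) < 0.05


def test_anomaly_hop_crossover(hop_ensemble):
    """Hop diffusion interpolates between the short-time and long-time
    plateaus of log(MSD/dt): the mid-range exponent sits strictly
    between 0 and 1."""
    curves = [sp.compute_msd(s.trajectory, 250) for s in hop_ensemble]
    ens = sp.ensemble_msd(curves)
    mid = sp.anomaly_curve([ens], fit_window=(0.5e-3, 5e-3))
    assert 0.05 < mid.alpha < 0.95
    # and the long-lag end rises back toward free diffusion
    late = sp.anomaly_curve([ens], fit_window=(10e-3, 25e-3))
    assert late.alpha > mid.alpha
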