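"""Synthetic movie rendering and the detect/localize/link pipeline."""
import math

import numpy as np
import pytest
from scipy.stats import rayleigh

import spthop as sp
from spthop import constants
from spthop.imaging import CameraModel, LinkParams, SpotDetectionParams


def _static_emitter(x_nm, y_nm, n_frames=1):
    pos = np.tile([[x_nm, y_nm]], (max(n_frames, 2), 1))
    return sp.Trajectory(pos, 1e-4)


def test_render_photon_conservation():
    """Before noise, total expected photons = emitter photons + background
    times area, exactly."""
    cam = CameraModel()
    tr = _static_emitter(32 * cam.pixel_nm, 32 * cam.pixel_nm)
    stack = sp.render_movie(
        [(tr, 120.0)], cam, (64, 64), background_photons=0.05, noise=False,
        n_frames=1,
    )
    assert stack.frames[0].sum() == pytest.approx(120.0 + 0.05 * 64 * 64, rel=1e-6)


def test_render_peak_pixel_expectation():
    """34 photons, SD 2.2 px, centered on a pixel: peak expectation 1.1."""
    cam = CameraModel()
    tr = _static_emitter(30 * cam.pixel_nm, 30 * cam.pixel_nm)
    stack = sp.render_movie([(tr, 34.0)], cam, (60, 60), psf_sd_px=2.2,
                            noise=False, n_frames=1)
    assert stack.frames[0].max() == pytest.approx(1.1, abs=0.01)


def test_render_readout_noise_scale():
    """With no emitters and no background, decoded electron SD matches a
    direct Monte Carlo of the same clipped-and-quantized 37 e- readout."""
    cam = CameraModel()
    stack = sp.render_movie([], cam, (320, 320), seed=3, n_frames=1)
    electrons = stack.frames[0].astype(float) * cam.electrons_per_count
    # independent oracle: same chain applied to raw normal draws
    rng = np.random.default_rng(99)
    raw = np.clip(rng.normal(0.0, cam.readout_rms, 320 * 320), 0, cam.full_well)
    oracle = (
        np.clip(np.rint(raw / cam.electrons_per_count), 0, cam.max_count)
        * cam.electrons_per_count
    )
    assert abs(electrons.std() / oracle.std() - 1.0) < 0.05


def test_digitization_preserves_expected_photons():
    """Noise-free gain (F=1, no readout): decoded photons equal the input
    detected photons in expectation within 2%."""
    cam = CameraModel(excess_f=1.0, readout_rms=1e-9)
    tr = _static_emitter(16 * cam.pixel_nm, 16 * cam.pixel_nm)
    # 60 photons keeps the peak pixel below the ~3.7-photon full well
    stack = sp.render_movie(
        [(tr, 60.0)], cam, (32, 32), seed=5, background_photons=0.2,
        n_frames=1,
    )
    decoded = sp.decode_photons(stack, cam).sum()
    expected = 60.0 + 0.2 * 32 * 32
    assert abs(decoded / expected - 1.0) < 0.02


def test_kapur_threshold_separates_bimodal():
    rng = np.random.default_rng(0)
    dark = rng.normal(0, 1, 4000)
    bright = rng.normal(10, 1, 1000)
    image = np.concatenate([dark, bright])
    thr = sp.kapur_threshold(image.reshape(50, 100))
    # the threshold keeps essentially all of the bright mode and rejects
    # the bulk of the dark one
    assert np.mean(bright >= thr) > 0.99
    assert np.mean(dark >= thr) < 0.10


def test_detect_spots_cases():
    cam = CameraModel()
    params = SpotDetectionParams()
    one = _static_emitter(20 * cam.pixel_nm, 24 * cam.pixel_nm)
    stack = sp.render_movie([(one, 150.0)], cam, (48, 48), seed=1,
                            background_photons=0.05, n_frames=1)
    photons = sp.decode_photons(stack, cam)
    found = sp.detect_spots(photons[0], params)
    assert len(found) == 1
    assert math.hypot(found[0][0] - 20, found[0][1] - 24) < 1.0
    # two spots 20 px apart
    other = _static_emitter(40 * cam.pixel_nm, 24 * cam.pixel_nm)
    stack2 = sp.render_movie([(one, 150.0), (other, 150.0)], cam, (64, 64),
                             seed=2, background_photons=0.05, n_frames=1)
    found2 = sp.detect_spots(sp.decode_photons(stack2, cam)[0], params)
    assert len(found2) == 2
    # empty frame
    assert sp.detect_spots(np.zeros((32, 32)), params) == []


def test_impulse_rejected_next_to_real_spot():
    """A hot pixel is not PSF-shaped: its normalized correlation stays low
    and its supra-threshold footprint falls below the 5-pixel area rule,
    so only the real spot is reported."""
    cam = CameraModel()
    tr = _static_emitter(20 * cam.pixel_nm, 24 * cam.pixel_nm)
    stack = sp.render_movie([(tr, 150.0)], cam, (48, 48), seed=4,
                            background_photons=0.05, n_frames=1)
    frame = sp.decode_photons(stack, cam)[0].copy()
    frame[33, 7] += 50.0  # impulse
    found = sp.detect_spots(frame, SpotDetectionParams())
    assert len(found) == 1
    assert math.hypot(found[0][0] - 20, found[0][1] - 24) < 1.0
    # and the area rule is actually in force: an absurd minimum kills all
    import dataclasses
    strict = dataclasses.replace(SpotDetectionParams(), min_area_px=10_000)
    assert sp.detect_spots(frame, strict) == []


def test_localize_exact_on_sampled_gaussian():
    """Noiseless sampled Gaussian at (10.30, 7.70) px recovered to 0.01 px."""
    yy, xx = np.mgrid[0:32, 0:32]
    x0, y0, s, A, B = 10.30, 7.70, 2.2, 5.0, 0.1
    frame = A * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s * s)) + B
    loc = sp.localize_spot(frame, (10.0, 8.0), SpotDetectionParams(),
                           pixel_nm=1.0)
    assert loc is not None
    assert loc.x_nm == pytest.approx(x0, abs=0.01)
    assert loc.y_nm == pytest.approx(y0, abs=0.01)
    assert loc.psf_sd_px == pytest.approx(s, abs=0.05)


def test_localize_edge_flagged():
    frame = np.ones((20, 20))
    assert sp.localize_spot(frame, (2.0, 2.0), SpotDetectionParams()) is None


def test_localization_precision_matches_mortensen():
    """Empirical localization scatter of a rendered 100-photon spot agrees
    with the Mortensen prediction within 25%."""
    cam = CameraModel(excess_f=1.2)
    params = SpotDetectionParams()
    bg_rate = 0.035
    true_x, true_y = 16.37 * cam.pixel_nm, 15.81 * cam.pixel_nm
    tr = _static_emitter(true_x, true_y, n_frames=200)
    stack = sp.render_movie([(tr, 100.0)], cam, (32, 32), seed=7,
                            background_photons=bg_rate, n_frames=200)
    photons = sp.decode_photons(stack, cam)
    xs, ys = [], []
    for f in range(200):
        loc = sp.localize_spot(photons[f], (16.0, 16.0), params, frame_index=f)
        if loc is not None:
            xs.append(loc.x_nm)
            ys.append(loc.y_nm)
    assert len(xs) > 150
    sigma_emp = 0.5 * (np.std(xs) + np.std(ys))
    # b: empirical SD of background photons per pixel in a blank corner
    b = float(photons[:, :6, :6].std())
    pred = sp.mortensen_precision(
        sp.MortensenParams(n_photons=100, s_nm=constants.PSF_SD_NM,
                           a_nm=cam.pixel_nm, b=b, f=cam.excess_f)
    )
    assert abs(sigma_emp / pred - 1.0) < 0.25


def test_link_gate_closed_form_matches_rayleigh():
    """Gate radius equals the Rayleigh quantile with per-axis variance
    2 D dt + 2 sigma^2."""
    d, dt, sig, p = 1.0, 1e-4, 30.0, 0.997
    v = 2 * d * 1e6 * dt + 2 * sig**2
    oracle = rayleigh.ppf(p, scale=math.sqrt(v))
    assert sp.link_gate_radius_nm(d, dt, sig, p) == pytest.approx(oracle, rel=1e-9)


def test_link_gate_monotonicity():
    base = sp.link_gate_radius_nm(1.0, 1e-4, 30.0, 0.997)
    assert sp.link_gate_radius_nm(2.0, 1e-4, 30.0, 0.997) > base
    assert sp.link_gate_radius_nm(1.0, 2e-4, 30.0, 0.997) > base
    assert sp.link_gate_radius_nm(1.0, 1e-4, 60.0, 0.997) > base
    assert sp.link_gate_radius_nm(1.0, 1e-4, 30.0, 0.999) > base


def _locs_from_positions(positions_by_frame):
    return {
        f: [
            sp.Localization(frame=f, x_nm=x, y_nm=y, amplitude=1, psf_sd_px=2,
                            background=0)
            for x, y in pts
        ]
        for f, pts in positions_by_frame.items()
    }


def test_link_single_and_separated_tracks():
    dt = 1e-4
    lp = LinkParams(expected_d=1.0, loc_sd_nm=10.0)
    moving = {f: [(f * 20.0, 0.0)] for f in range(10)}
    tracks = sp.link_spots(_locs_from_positions(moving), lp, dt)
    assert len(tracks) == 1 and len(tracks[0]) == 10
    # two emitters far apart: two tracks, no identity switches
    double = {f: [(f * 20.0, 0.0), (f * 20.0, 50000.0)] for f in range(10)}
    tracks2 = sp.link_spots(_locs_from_positions(double), lp, dt)
    assert len(tracks2) == 2
    for tr in tracks2:
        ys = {round(l.y_nm) for l in tr.localizations}
        assert len(ys) == 1


def test_gap_close_rules():
    dt = 1e-4
    lp = LinkParams(expected_d=1.0, loc_sd_nm=10.0, max_gap=3)
    for gap, n_expected in [(3, 1), (4, 2)]:
        frames = {f: [(0.0, 0.0)] for f in range(5)}
        frames.update({f: [(0.0, 0.0)] for f in range(5 + gap, 10 + gap)})
        tracks = sp.link_spots(_locs_from_positions(frames), lp, dt)
        merged = sp.gap_close(tracks, lp, dt)
        assert len(merged) == n_expected


def test_on_off_periods():
    assert sp.on_off_periods(np.ones(10), 0.5)["on"] == [10]
    pattern = np.array([1] * 5 + [0] * 2 + [1] * 5, dtype=float)
    res = sp.on_off_periods(pattern, 0.5)
    assert res["on"] == [5, 5]
    assert res["on_gap3"] == [12]
    pattern2 = np.array([1] * 5 + [0] * 4 + [1] * 5, dtype=float)
    assert sp.on_off_periods(pattern2, 0.5)["on_gap3"] == [5, 5]


def test_round_trip_simulate_render_track():
    """A bright moving emitter is recovered frame-for-frame: >=95% of
    frames linked into one track with RMSE below twice the Mortensen
    prediction."""
    cam = CameraModel()
    dt, n_frames, photons = 1e-4, 60, 150.0
    truth = sp.simulate_brownian_trajectory(0.5, n_frames, dt, seed=17)
    center = 32 * cam.pixel_nm
    shifted = sp.Trajectory(truth.positions + center, dt)
    stack = sp.render_movie([(shifted, photons)], cam, (64, 64), seed=18,
                            background_photons=0.03, n_frames=n_frames)
    frames = sp.decode_photons(stack, cam)
    det_params = SpotDetectionParams()
    locs = {}
    for f in range(n_frames):
        frame_locs = []
        for c in sp.detect_spots(frames[f], det_params):
            loc = sp.localize_spot(frames[f], c, det_params, frame_index=f)
            if loc is not None:
                frame_locs.append(loc)
        locs[f] = frame_locs
    # expected localization error ~30 nm: full-well clipping of the peak
    # pixel makes the true scatter larger than the shot-noise ideal
    lp = LinkParams(expected_d=0.5, loc_sd_nm=30.0)
    tracks = sp.gap_close(sp.link_spots(locs, lp, dt), lp, dt)
    best = max(tracks, key=len)
    assert len(best) >= 0.95 * n_frames
    errs = []
    for loc in best.localizations:
        tx, ty = shifted.positions[loc.frame]
        errs.append((loc.x_nm - tx) ** 2 + (loc.y_nm - ty) ** 2)
    rmse_per_axis = math.sqrt(np.mean(errs) / 2.0)
    pred = sp.mortensen_precision(
        sp.MortensenParams(n_photons=photons, s_nm=constants.PSF_SD_NM,
                           a_nm=cam.pixel_nm, b=0.2, f=cam.excess_f)
    )
    assert rmse_per_axis < 2 * pred
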