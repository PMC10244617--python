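"""Synthetic single-molecule movies and their re-detection pipeline.

The renderer pushes expected photons (pixelized Gaussian PSF + uniform
background) through the camera noise chain: Poisson photon statistics,
per-photon stochastic intensifier gain (Gamma-distributed so the effective
excess noise factor equals F), Gaussian readout noise, full-well clipping
and digitization.  The detection side mirrors the tracking procedure used
for real movies: normalized cross-correlation with a Gaussian kernel,
maximum-entropy (Kapur) thresholding, connected-component spot candidates,
Gaussian PSF least-squares localization with fixed local background, gated
nearest-neighbour linking, and gap closing of short dark periods.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from skimage.feature import match_template
from skimage.measure import label, regionprops

from . import constants
from .photophysics import PixelizedPsf, pixelized_psf_image
from .trajectory import Trajectory
from .units import d_um2s_to_nm2s


@dataclass
class CameraModel:
    """Intensified-CMOS noise chain constants."""

    qe: float = constants.QE_PHOTOCATHODE
    overall_gain: float = constants.OVERALL_GAIN
    excess_f: float = 1.2
    readout_rms: float = constants.READOUT_NOISE_E
    full_well: float = constants.FULL_WELL_E
    pixel_nm: float = constants.PIXEL_NM
    bit_depth: int = 10

    def __post_init__(self) -> None:
        if self.excess_f < 1:
            raise ValueError("excess_f must be >= 1")
        if self.bit_depth not in (10, 12, 16):
            raise ValueError("bit_depth must be 10, 12 or 16")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def electrons_per_count(self) -> float:
        return self.full_well / self.max_count

    @property
    def gain_conversion(self) -> float:
        """Photons per camera count (counts -> detected photons)."""
        return self.electrons_per_count / self.overall_gain


@dataclass
class FrameStack:
    """An image sequence in camera counts (or photons when decoded)."""

    frames: np.ndarray  # (T, H, W)
    frame_time: float
    pixel_nm: float
    units: str = "counts"


@dataclass
class SpotDetectionParams:
    """Cross-correlation detection parameters."""

    kernel_sd_nm: float = constants.PSF_SD_NM
    min_area_px: int = 5
    fit_region_px: int = 15
    pixel_nm: float = constants.PIXEL_NM

    def __post_init__(self) -> None:
        if self.fit_region_px % 2 == 0:
            raise ValueError("fit_region_px must be odd")

    @property
    def kernel_sd_px(self) -> float:
        return self.kernel_sd_nm / self.pixel_nm


@dataclass
class Localization:
    """A sub-pixel Gaussian-fit localization."""

    frame: int
    x_nm: float
    y_nm: float
    amplitude: float
    psf_sd_px: float
    background: float


@dataclass
class LinkParams:
    """Gated nearest-neighbour linking parameters."""

    expected_d: float  # um^2/s
    loc_sd_nm: float = 0.0
    gate_prob: float = 0.997
    max_gap: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.gate_prob < 1:
            raise ValueError("gate_prob must be in (0, 1)")


@dataclass
class Track:
    """A linked sequence of localizations (frames may have gaps after
    gap closing; gaps are recorded, never interpolated)."""

    localizations: list[Localization] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([l.frame for l in self.localizations], dtype=int)

    def __len__(self) -> int:
        return len(self.localizations)

    def to_trajectory(self, frame_time: float, track_id: int = 0) -> Trajectory:
        """Convert to a Trajectory; requires contiguous frames."""
        frames = self.frames
        if np.any(np.diff(frames) != 1):
            raise ValueError("track has frame gaps; split before converting")
        pos = np.array([[l.x_nm, l.y_nm] for l in self.localizations])
        return Trajectory(pos, frame_time, id=track_id)


def render_movie(
    emitters: list[tuple[Trajectory, float]],
    cam: CameraModel,
    shape: tuple[int, int],
    seed: int = 0,
    background_photons: float = 0.0,
    psf_sd_px: float | None = None,
    n_frames: int | None = None,
    noise: bool = True,
) -> FrameStack:
    """Render a synthetic movie in camera counts.

    ``emitters`` pairs a trajectory (nm coordinates) with its mean detected
    photons per frame.  Per pixel and frame: Poisson(expected photons) ->
    per-photon Gamma gain with mean ``overall_gain`` and variance
    (F^2 - 1) * gain^2 -> additive Gaussian readout noise -> clip at the
    full well -> digitize.  ``noise=False`` returns the expected photon
    image (units='photons') for conservation checks.
    """
    if psf_sd_px is None:
        psf_sd_px = constants.PSF_SD_PX
    H, W = shape
    if n_frames is None:
        n_frames = max(tr.n_frames for tr, _ in emitters) if emitters else 1
    rng = np.random.default_rng(seed)
    expected = np.full((n_frames, H, W), float(background_photons))
    for tr, photons in emitters:
        for f in range(min(tr.n_frames, n_frames)):
            cx = tr.positions[f, 0] / cam.pixel_nm
            cy = tr.positions[f, 1] / cam.pixel_nm
            if not (0 <= cx < W and 0 <= cy < H):
                warnings.warn(
                    f"emitter {tr.id} off-frame at frame {f}; clipped", stacklevel=2
                )
                cx = min(max(cx, 0.0), W - 1.0)
                cy = min(max(cy, 0.0), H - 1.0)
            psf = PixelizedPsf(i_total=photons, center=(cx, cy), s=psf_sd_px)
            expected[f] += pixelized_psf_image(psf, shape)
    if not noise:
        return FrameStack(expected, frame_time=0.0, pixel_nm=cam.pixel_nm,
                          units="photons")

    photons_det = rng.poisson(expected).astype(np.float64)
    # per-photon Gamma gain: shape k = 1/(F^2-1) reproduces excess factor F;
    # the sum of n i.i.d. Gamma(k, gain/k) draws is Gamma(n*k, gain/k)
    if cam.excess_f > 1.0:
        k = 1.0 / (cam.excess_f**2 - 1.0)
        electrons = np.zeros_like(photons_det)
        nz = photons_det > 0
        electrons[nz] = rng.gamma(photons_det[nz] * k, cam.overall_gain / k)
    else:
        electrons = photons_det * cam.overall_gain
    electrons += rng.normal(0.0, cam.readout_rms, size=electrons.shape)
    electrons = np.clip(electrons, 0.0, cam.full_well)
    counts = np.clip(
        np.rint(electrons / cam.electrons_per_count), 0, cam.max_count
    ).astype(np.uint16)
    return FrameStack(counts, frame_time=0.0, pixel_nm=cam.pixel_nm, units="counts")


def decode_photons(stack: FrameStack, cam: CameraModel) -> np.ndarray:
    """Counts -> detected photons via the gain conversion factor."""
    if stack.units == "photons":
        return stack.frames
    return stack.frames.astype(np.float64) * cam.gain_conversion


def kapur_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Kapur's maximum-entropy threshold.

    The image is quantized to ``n_bins`` grey levels; the threshold
    maximizes the sum of the Shannon entropies of the below- and
    above-threshold grey-level distributions.
    """
    flat = image.ravel().astype(np.float64)
    lo, hi = float(flat.min()), float(flat.max())
    if hi <= lo:
        return lo
    hist, edges = np.histogram(flat, bins=n_bins, range=(lo, hi))
    p = hist / hist.sum()
    cum = np.cumsum(p)

    def entropy(prob: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(prob > 0, prob * np.log(prob), 0.0)
        return term

    ent = entropy(p)
    cum_ent = np.cumsum(ent)
    total_ent = cum_ent[-1]
    best_t, best_val = 0, -np.inf
    for t in range(n_bins - 1):
        w0, w1 = cum[t], 1.0 - cum[t]
        if w0 <= 0 or w1 <= 0:
            continue
        h0 = math.log(w0) - cum_ent[t] / w0
        h1 = math.log(w1) - (total_ent - cum_ent[t]) / w1
        if h0 + h1 > best_val:
            best_val, best_t = h0 + h1, t
    return float(edges[best_t + 1])


def _gaussian_kernel(sd_px: float) -> np.ndarray:
    r = max(int(math.ceil(3 * sd_px)), 2)
    g = np.arange(-r, r + 1)
    k = np.exp(-(g**2) / (2 * sd_px**2))
    return np.outer(k, k)


def detect_spots(
    frame: np.ndarray, params: SpotDetectionParams | None = None
) -> list[tuple[float, float]]:
    """Detect spot candidates in one frame (photon units).

    Normalized cross-correlation against a Gaussian kernel, Kapur
    maximum-entropy threshold on the correlation image, 8-connected
    components of area >= min_area_px; returns (x, y) centroids in pixels.
    """
    params = params or SpotDetectionParams()
    if frame.size == 0 or frame.max() == frame.min():
        return []
    kernel = _gaussian_kernel(params.kernel_sd_px)
    r = kernel.shape[0] // 2
    # valid-mode correlation: the border band (kernel radius) is excluded,
    # since padded partial windows produce spurious edge responses
    corr = match_template(frame.astype(np.float64), kernel, pad_input=False)
    # maximum-entropy threshold with a robust noise floor: on sparse frames
    # (a handful of spots) the background mode dominates the histogram and
    # pulls the entropy optimum into the noise, so the floor median +
    # 3.5 * 1.4826 * MAD keeps pure-noise correlation blobs out
    mad_sigma = 1.4826 * float(np.median(np.abs(corr - np.median(corr))))
    noise_floor = float(np.median(corr)) + 3.5 * mad_sigma
    thr = max(kapur_threshold(corr), noise_floor)
    mask = corr >= thr
    labels = label(mask, connectivity=2)
    out = []
    for region in regionprops(labels, intensity_image=corr):
        if region.area >= params.min_area_px:
            cy, cx = region.centroid_weighted
            out.append((float(cx) + r, float(cy) + r))
    return out


def localize_spot(
    frame: np.ndarray,
    centroid_px: tuple[float, float],
    params: SpotDetectionParams | None = None,
    pixel_nm: float | None = None,
    frame_index: int = 0,
) -> Localization | None:
    """Sub-pixel localization: least-squares fit of
    A*exp(-((x-x0)^2+(y-y0)^2)/(2 s^2)) + B over the circular fit region.

    B is fixed to the measured local background (mean intensity of the
    square region outside the circle).  Returns None when the fit fails or
    the region leaves the frame.
    """
    params = params or SpotDetectionParams()
    pixel_nm = pixel_nm if pixel_nm is not None else params.pixel_nm
    r = params.fit_region_px // 2
    cx, cy = centroid_px
    ix, iy = int(round(cx)), int(round(cy))
    H, W = frame.shape
    if not (r <= ix < W - r and r <= iy < H - r):
        return None
    patch = frame[iy - r : iy + r + 1, ix - r : ix + r + 1].astype(np.float64)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    circle = xx**2 + yy**2 <= r**2
    background = float(patch[~circle].mean()) if np.any(~circle) else 0.0
    data = patch[circle]
    xs, ys = xx[circle].astype(float), yy[circle].astype(float)

    a0 = max(float(patch.max() - background), 1e-6)
    s0 = params.kernel_sd_px

    def resid(p):
        a, x0, y0, s = p
        model = a * np.exp(-((xs - x0) ** 2 + (ys - y0) ** 2) / (2 * s**2)) + background
        return model - data

    try:
        sol = least_squares(
            resid, x0=[a0, 0.0, 0.0, s0],
            bounds=([0.0, -r, -r, 0.1], [np.inf, r, r, 4.0 * s0]),
        )
    except Exception:
        return None
    if not sol.success:
        return None
    a, x0, y0, s = sol.x
    return Localization(
        frame=frame_index,
        x_nm=(ix + x0) * pixel_nm,
        y_nm=(iy + y0) * pixel_nm,
        amplitude=float(a),
        psf_sd_px=float(s),
        background=background,
    )


def link_gate_radius_nm(
    expected_d: float, frame_time: float, loc_sd_nm: float, gate_prob: float = 0.997,
    n_frames_gap: int = 1,
) -> float:
    """Closed-form Rayleigh-quantile linking gate.

    Per-axis displacement variance over g frames is v = 2 D g dt + 2 sigma^2
    (both frames' localization errors count), so the 2-D displacement is
    Rayleigh and P(r <= R) = p gives R = sqrt(-2 v ln(1 - p)).
    """
    v = 2.0 * d_um2s_to_nm2s(expected_d) * frame_time * n_frames_gap + 2.0 * loc_sd_nm**2
    return math.sqrt(-2.0 * v * math.log(1.0 - gate_prob))


def link_spots(
    localizations: dict[int, list[Localization]],
    params: LinkParams,
    frame_time: float,
) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking within the gate.

    ``localizations`` maps frame index -> detections in that frame.
    Unmatched detections start new tracks.
    """
    gate = link_gate_radius_nm(
        params.expected_d, frame_time, params.loc_sd_nm, params.gate_prob
    )
    tracks: list[Track] = []
    active: list[Track] = []
    for f in sorted(localizations):
        dets = list(localizations[f])
        # only tracks seen in the immediately preceding frame may continue
        still_active = []
        for tr in active:
            if tr.localizations[-1].frame == f - 1:
                still_active.append(tr)
            else:
                tracks.append(tr)
        active = still_active
        new_active: list[Track] = []
        candidates = []
        for ti, tr in enumerate(active):
            last = tr.localizations[-1]
            for di, det in enumerate(dets):
                dist = math.hypot(det.x_nm - last.x_nm, det.y_nm - last.y_nm)
                if dist <= gate:
                    candidates.append((dist, ti, di))
        candidates.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for _, ti, di in candidates:
            if ti in used_t or di in used_d:
                continue
            active[ti].localizations.append(dets[di])
            used_t.add(ti)
            used_d.add(di)
            new_active.append(active[ti])
        for ti, tr in enumerate(active):
            if ti not in used_t:
                tracks.append(tr)  # track ended
        for di, det in enumerate(dets):
            if di not in used_d:
                t = Track([det])
                new_active.append(t)
        active = new_active
    tracks.extend(active)
    return [t for t in tracks if len(t) > 0]


def gap_close(
    tracks: list[Track],
    params: LinkParams,
    frame_time: float,
) -> list[Track]:
    """Merge track fragments separated by <= max_gap dark frames.

    A fragment pair merges when the second starts 1..max_gap+1 frames after
    the first ends and the displacement lies within the (gap+1)-frame gate.
    Merged gaps are recorded as missing frames, never interpolated.
    """
    frags = sorted(tracks, key=lambda t: t.localizations[0].frame)
    merged: list[Track] = []
    open_frags = list(frags)
    while open_frags:
        cur = open_frags.pop(0)
        changed = True
        while changed:
            changed = False
            last = cur.localizations[-1]
            best = None
            for i, cand in enumerate(open_frags):
                first = cand.localizations[0]
                gap = first.frame - last.frame - 1
                if gap < 1 or gap > params.max_gap:
                    continue
                gate = link_gate_radius_nm(
                    params.expected_d, frame_time, params.loc_sd_nm,
                    params.gate_prob, n_frames_gap=gap + 1,
                )
                dist = math.hypot(first.x_nm - last.x_nm, first.y_nm - last.y_nm)
                if dist <= gate and (best is None or dist < best[0]):
                    best = (dist, i)
            if best is not None:
                cand = open_frags.pop(best[1])
                cur.localizations.extend(cand.localizations)
                changed = True
        merged.append(cur)
    return merged


def on_off_periods(
    trace: np.ndarray, threshold: float, gaps: tuple[int, ...] = (1, 2, 3)
) -> dict:
    """On/off durations of an intensity trace by run-length encoding.

    Returns the raw on-periods, the off-periods, and for each g in ``gaps``
    the on-periods after closing off-periods of length <= g.
    """
    on = np.asarray(trace) >= threshold

    def runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
        out = []
        start = 0
        for i in range(1, len(mask) + 1):
            if i == len(mask) or mask[i] != mask[start]:
                out.append((start, i, bool(mask[start])))
                start = i
        return out

    def on_lengths(mask: np.ndarray) -> list[int]:
        return [b - a for a, b, v in runs(mask) if v]

    result = {
        "on": on_lengths(on),
        "off": [b - a for a, b, v in runs(on) if not v],
    }
    for g in gaps:
        closed = on.copy()
        for a, b, v in runs(on):
            # interior off-runs of length <= g are closed
            if not v and b - a <= g and a > 0 and b < len(on):
                closed[a:b] = True
        result[f"on_gap{g}"] = on_lengths(closed)
    return result
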