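"""Detection of hop instants as Transient Increases of Local Diffusion (TILD).

A molecule hopping between two membrane compartments transiently samples a
larger region than either compartment alone, so the *local* effective
diffusion coefficient rises at the hop.  For a window of n frames starting
at frame m, let R_MAX(m,n) be the largest distance of any of the n points
from their centroid.  The relative local diffusion coefficient is

    D_rel(m,n) = R_MAX^2(m,n) / (4 n dt D_2-4),

normalized by the trajectory's short-term diffusion coefficient D_2-4.
For this normalization D_2-4 is the *average* diffusion coefficient over
the 2dt-4dt interval — the mean of (MSD(n dt) - 4 sigma_xy^2)/(4 n dt)
over n = 2, 3, 4, computed on the raw (unsmoothed) trajectory with the
localization-error offset removed (:func:`short_term_secant_d`).  For
compartmentalized motion this secant coefficient reflects the fast
intra-compartment diffusion (several um^2/s) rather than the much smaller
incremental slope between those lags, which is what gives the H statistic
its sensitivity: windows confined to one compartment then have
1/D_rel >> 1, so a single-frame window shift across a compartment change
moves H by more than 1, while for free Brownian motion D_rel stays near 1
and H stays small.  Hops are flagged by

    H(m,n) = | 1/D_rel(m+1,n) - 1/D_rel(m,n) |,

which spikes when windows starting at m and m+1 straddle a compartment
change.  The trajectory is scanned both forward (anterograde) and
time-reversed (retrograde), giving each boundary m a combined pool of
(N - m - n_min) + (m + 2 - n_min) windows (= N - 40 at n_min = 21).  A
boundary where more than ``window_fraction`` of its windows have
H >= ``h_threshold`` is a TILD; contiguous flagged runs collapse to the
frame with the highest qualifying fraction, and TILDs closer than
``min_separation_s`` keep only the stronger one.

Compartment residency times are the gaps between consecutive TILDs; their
distribution is exponential with lifetime tau = L^2 / (4 D_MACRO) under
idealized hop diffusion, estimated here by a left-truncated exponential fit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .msd import compute_msd
from .trajectory import Trajectory
from .units import d_um2s_to_nm2s

try:  # pragma: no cover
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class TildParams:
    """Detection thresholds.

    Defaults are the standard operating point for 1,000-frame trajectories
    at 10 kHz: windows of at least 21 frames, a window qualifies when
    H >= 1, a boundary is a TILD when >20% of its windows qualify, TILDs
    closer than 2 ms merge, residencies shorter than 4 ms are discarded
    from lifetime fits, and a 3-frame running average is applied first.
    """

    n_min: int = 21
    h_threshold: float = 1.0
    window_fraction: float = 0.20
    min_separation_s: float = 2e-3
    min_residency_s: float = 4e-3
    smooth_width: int = 3
    m_stride: int = 1
    loc_error_sd: float = 0.0  # per-coordinate sigma_xy (nm) removed from D_2-4

    def __post_init__(self) -> None:
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")
        if not 0 < self.window_fraction < 1:
            raise ValueError("window_fraction must be in (0, 1)")
        if self.smooth_width < 1 or self.smooth_width % 2 == 0:
            raise ValueError("smooth_width must be odd and >= 1")
        if self.m_stride < 1:
            raise ValueError("m_stride must be >= 1")


@dataclass
class TildMap:
    """D_rel / H / R_MAX maps over (start frame m, window size n).

    Map entry [m, j] corresponds to window size n = n_min + j; entries
    outside n_min <= n <= N - m are NaN.  The retrograde maps are the
    anterograde maps of the time-reversed trajectory.
    """

    d_rel: np.ndarray
    h: np.ndarray
    r_max: np.ndarray
    retro_d_rel: np.ndarray
    retro_h: np.ndarray
    retro_r_max: np.ndarray
    n_min: int
    frame_time: float
    d_2_4: float


@dataclass
class TildResult:
    """Detected TILD instants and the residencies between them."""

    hop_frames: np.ndarray
    residencies: np.ndarray
    fractions: np.ndarray = field(default_factory=lambda: np.empty(0))
    unclassifiable: bool = False


@dataclass
class DwellFit:
    """Left-truncated exponential lifetime fit."""

    tau: float
    se: float
    t_min: float
    n_durations: int
    degenerate: bool = False


def short_term_secant_d(traj: Trajectory, loc_error_sd: float = 0.0) -> float:
    """Average short-term diffusion coefficient over the 2dt-4dt interval.

    Mean of (MSD_2D(n dt) - 4 sigma^2) / (4 n dt) for n = 2, 3, 4, in
    um^2/s.  ``loc_error_sd`` is the per-coordinate localization error
    sigma_xy (nm) whose offset 4 sigma^2 is removed before forming the
    secants; for simulated noise it is known exactly, for experimental
    data it comes from the ensemble MSD intercept.  May be <= 0 on
    pathological input (caller must treat that as unclassifiable).
    """
    curve = compute_msd(traj, max_lag_frames=4)
    offset = 4.0 * loc_error_sd**2
    secants = [
        (curve.msd_2d[n - 1] - offset) / (4.0 * n * traj.frame_time)
        for n in (2, 3, 4)
    ]
    return float(np.mean(secants)) / 1e6  # nm^2/s -> um^2/s


def smooth_running_average(traj: Trajectory, width: int = 3) -> Trajectory:
    """Centered moving average per coordinate; endpoints use the shorter
    one-sided windows, so the length is preserved.  width=1 is the identity."""
    if width % 2 == 0 or width < 1:
        raise ValueError("width must be odd and >= 1")
    if traj.n_frames < width:
        raise ValueError("trajectory shorter than the smoothing window")
    if width == 1:
        return Trajectory(traj.positions.copy(), traj.frame_time, traj.id)
    h = width // 2
    N = traj.n_frames
    cs = np.vstack([np.zeros((1, 2)), np.cumsum(traj.positions, axis=0)])
    lo = np.maximum(np.arange(N) - h, 0)
    hi = np.minimum(np.arange(N) + h + 1, N)
    out = (cs[hi] - cs[lo]) / (hi - lo)[:, None]
    return Trajectory(out, traj.frame_time, traj.id)


@njit(cache=True)
def _rmax_map_kernel(x, y, n_min, row_mask):
    """R_MAX^2 over all (m, n) windows; entry [m, n - n_min], NaN invalid.

    Matches the naive definition exactly: centroid of the n window points,
    maximal squared distance of a window point from it.  row_mask[m] skips
    rows (m-stride support)."""
    N = x.shape[0]
    n_cols = N - n_min + 1
    out = np.full((N, n_cols), np.nan)
    sx = np.zeros(N + 1)
    sy = np.zeros(N + 1)
    for i in range(N):
        sx[i + 1] = sx[i] + x[i]
        sy[i + 1] = sy[i] + y[i]
    for m in range(0, N - n_min + 1):
        if not row_mask[m]:
            continue
        n_max = N - m
        for n in range(n_min, n_max + 1):
            cx = (sx[m + n] - sx[m]) / n
            cy = (sy[m + n] - sy[m]) / n
            r2 = 0.0
            for i in range(m, m + n):
                dx = x[i] - cx
                dy = y[i] - cy
                d2 = dx * dx + dy * dy
                if d2 > r2:
                    r2 = d2
            out[m, n - n_min] = r2
    return out


def _rmax_map_reference(x, y, n_min, row_mask):
    """Naive NumPy mirror of _rmax_map_kernel (test oracle / fallback)."""
    N = len(x)
    pts = np.column_stack([x, y])
    out = np.full((N, N - n_min + 1), np.nan)
    for m in range(0, N - n_min + 1):
        if not row_mask[m]:
            continue
        for n in range(n_min, N - m + 1):
            w = pts[m : m + n]
            c = w.mean(axis=0)
            out[m, n - n_min] = np.max(np.sum((w - c) ** 2, axis=1))
    return out


def _rmax_squared_map(pos: np.ndarray, n_min: int, row_mask: np.ndarray) -> np.ndarray:
    fn = _rmax_map_kernel if _HAVE_NUMBA else _rmax_map_reference
    return fn(
        np.ascontiguousarray(pos[:, 0]),
        np.ascontiguousarray(pos[:, 1]),
        n_min,
        row_mask,
    )


def _h_from_drel(d_rel: np.ndarray) -> np.ndarray:
    """H[m, j] = |1/D_rel[m+1, j] - 1/D_rel[m, j]| (NaN where undefined)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / d_rel
        h = np.full_like(d_rel, np.nan)
        h[:-1] = np.abs(inv[1:] - inv[:-1])
    return h


def compute_tild_map(
    traj: Trajectory,
    d_2_4: float,
    params: TildParams | None = None,
) -> TildMap:
    """D_rel, H and R_MAX maps for both scan directions.

    ``d_2_4`` (um^2/s) must come from the *unsmoothed* trajectory; the
    positions passed here are used as-is (apply smoothing beforehand for
    the standard pipeline).
    """
    params = params or TildParams()
    if d_2_4 <= 0:
        raise ValueError("d_2_4 must be > 0")
    N = traj.n_frames
    if N < 2 * params.n_min:
        raise ValueError(f"trajectory too short for TILD analysis (N < {2 * params.n_min})")
    n_min = params.n_min
    dt = traj.frame_time
    norm = 4.0 * dt * d_um2s_to_nm2s(d_2_4)

    if params.m_stride == 1:
        row_mask = np.ones(N, dtype=np.bool_)
    else:
        row_mask = np.zeros(N, dtype=np.bool_)
        row_mask[:: params.m_stride] = True
        row_mask[1 :: params.m_stride] = True  # H needs rows m and m+1

    n_grid = np.arange(n_min, N + 1, dtype=np.float64)
    r2_a = _rmax_squared_map(traj.positions, n_min, row_mask)
    r2_r = _rmax_squared_map(traj.positions[::-1], n_min, row_mask)
    d_rel_a = r2_a / (norm * n_grid[None, :])
    d_rel_r = r2_r / (norm * n_grid[None, :])
    return TildMap(
        d_rel=d_rel_a,
        h=_h_from_drel(d_rel_a),
        r_max=np.sqrt(r2_a),
        retro_d_rel=d_rel_r,
        retro_h=_h_from_drel(d_rel_r),
        retro_r_max=np.sqrt(r2_r),
        n_min=n_min,
        frame_time=dt,
        d_2_4=d_2_4,
    )


def _qualifying_fractions(
    tmap: TildMap, params: TildParams, N: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-boundary qualifying-window fraction, combining both directions.

    Boundary m sits between frames m and m+1.  Anterograde windows are
    H(m, n), n in [n_min, N-m-1]; retrograde windows are H(k, n) of the
    reversed trajectory at k = N-2-m, n in [n_min, m+1].
    """
    qual_a = np.nansum(tmap.h >= params.h_threshold, axis=1).astype(float)
    tot_a = np.sum(~np.isnan(tmap.h), axis=1).astype(float)
    qual_r = np.nansum(tmap.retro_h >= params.h_threshold, axis=1).astype(float)
    tot_r = np.sum(~np.isnan(tmap.retro_h), axis=1).astype(float)

    boundaries = np.arange(N - 1)
    k = N - 2 - boundaries
    qual = qual_a[boundaries] + qual_r[k]
    tot = tot_a[boundaries] + tot_r[k]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, qual / tot, np.nan)
    return frac, tot


def detect_tilds(
    traj: Trajectory,
    params: TildParams | None = None,
    d_2_4: float | None = None,
) -> TildResult:
    """Run the full TILD pipeline on one trajectory.

    Steps: secant D_2-4 from the raw trajectory (offset-corrected with
    ``params.loc_error_sd``, unless an explicit ``d_2_4`` in um^2/s is
    given); running-average smoothing; D_rel and H maps in both
    directions; per-boundary qualifying fraction; flagged-run merging;
    minimum-separation enforcement.
    """
    params = params or TildParams()
    if d_2_4 is None:
        d_2_4 = short_term_secant_d(traj, params.loc_error_sd)
    if d_2_4 <= 0:
        return TildResult(
            hop_frames=np.empty(0, dtype=int),
            residencies=np.empty(0),
            unclassifiable=True,
        )
    smoothed = smooth_running_average(traj, params.smooth_width)
    tmap = compute_tild_map(smoothed, d_2_4, params)
    N = traj.n_frames
    frac, tot = _qualifying_fractions(tmap, params, N)

    flagged = np.where((tot > 0) & (frac > params.window_fraction))[0]
    # merge contiguous flagged boundaries (allowing stride-sized gaps) into
    # one instant each: the boundary with the maximal fraction, ties earliest
    candidates: list[tuple[int, float]] = []
    if len(flagged):
        run_start = 0
        for i in range(1, len(flagged) + 1):
            if i == len(flagged) or flagged[i] - flagged[i - 1] > params.m_stride:
                run = flagged[run_start:i]
                best = run[np.argmax(frac[run])]
                candidates.append((int(best), float(frac[best])))
                run_start = i

    # enforce minimum separation, keeping the stronger of close TILDs
    min_sep = max(int(round(params.min_separation_s / traj.frame_time)), 1)
    kept: list[tuple[int, float]] = []
    for fr, strength in sorted(candidates, key=lambda c: -c[1]):
        if all(abs(fr - k[0]) >= min_sep for k in kept):
            kept.append((fr, strength))
    kept.sort()
    hop_frames = np.array([k[0] for k in kept], dtype=int)
    fractions = np.array([k[1] for k in kept])
    residencies = np.diff(hop_frames) * traj.frame_time
    return TildResult(hop_frames=hop_frames, residencies=residencies,
                      fractions=fractions)


def residency_durations(result: TildResult, min_residency_s: float = 4e-3) -> np.ndarray:
    """Dwell durations between consecutive TILDs, >= min_residency_s.

    The intervals before the first and after the last TILD are censored and
    never enter (residencies are between-TILD gaps by construction)."""
    if len(result.hop_frames) < 2:
        return np.empty(0)
    return result.residencies[result.residencies >= min_residency_s]


def fit_dwell_lifetime(
    durations: np.ndarray,
    t_min: float,
    method: str = "mle",
    n_bins: int = 30,
    window_s: float | None = None,
) -> DwellFit:
    """Exponential lifetime of left-truncated dwell durations.

    ``method="mle"``: plain MLE for an exponential truncated at t_min,
    tau = mean(durations) - t_min, with SE = tau/sqrt(n) (the 68.3%
    interval half-width).  ``method="binned"`` least-squares-fits
    A*exp(-t/tau) to the histogram of durations.

    ``method="window"`` additionally corrects the length-biased sampling
    that arises when complete dwells must fit inside a finite recording of
    duration ``window_s``: a dwell of length d is observed with relative
    probability (window_s - d), so the observed density is
    e^(-d/tau) (window_s - d) on [t_min, window_s] and the plain MLE is
    biased low by roughly tau^2/window_s.  The window MLE solves
    E[d | tau] = mean(durations) under that density; use it whenever the
    dwells come from fixed-length trajectories that are not much longer
    than the lifetime itself.
    """
    durations = np.asarray(durations, dtype=float)
    if len(durations) < 20:
        raise ValueError("need at least 20 durations for a lifetime fit")
    if np.any(durations < t_min):
        raise ValueError("all durations must be >= t_min")
    if method == "mle":
        tau = float(np.mean(durations) - t_min)
    elif method == "window":
        if window_s is None or window_s <= t_min:
            raise ValueError("method='window' needs window_s > t_min")
        from scipy.optimize import brentq

        grid = np.linspace(t_min, window_s, 2000)

        def model_mean(tau_try: float) -> float:
            # anchored at t_min to avoid underflow for tiny tau
            w = np.exp(-(grid - t_min) / tau_try) * (window_s - grid)
            return float(np.trapezoid(grid * w, grid) / np.trapezoid(w, grid))

        target = float(np.mean(durations))
        # the model mean is bounded above by the mid-window average even as
        # tau -> inf; clamp to the solvable range
        lo, hi = 1e-6, 100.0 * window_s
        if target <= model_mean(lo):
            tau = 0.0
        elif target >= model_mean(hi):
            tau = float("inf")
        else:
            tau = float(brentq(lambda t: model_mean(t) - target, lo, hi))
    elif method == "binned":
        from scipy.optimize import curve_fit

        counts, edges = np.histogram(durations, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ok = counts > 0
        tau0 = max(float(np.mean(durations) - t_min), 1e-6)
        popt, _ = curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            centers[ok],
            counts[ok],
            p0=[counts.max(), tau0],
        )
        tau = float(popt[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    n = len(durations)
    degenerate = tau <= 0
    se = tau / math.sqrt(n) if tau > 0 else float("nan")
    return DwellFit(tau=tau, se=se, t_min=t_min, n_durations=n, degenerate=degenerate)


def dwell_from_L_D(L_nm: float, d_macro: float) -> float:
    """Closed-form mean compartment dwell time tau = L^2 / (4 D_MACRO) in s
    (L in nm, D_MACRO in um^2/s)."""
    if L_nm <= 0 or d_macro <= 0:
        raise ValueError("L and D_MACRO must be positive")
    L_um = L_nm / 1000.0
    return (L_um * L_um) / (4.0 * d_macro)


def hop_detection_scores(
    detected_frames: np.ndarray,
    true_frames: np.ndarray,
    tol_frames: int,
) -> tuple[int, int]:
    """Within-tolerance hop scoring: (true hops detected, correct detections).

    A true hop counts as detected when any detection lies within
    ``tol_frames``; a detection counts as correct when any true hop does.
    Hops cluster in bursts (a molecule that has just crossed a barrier often
    re-crosses within a couple of milliseconds) while detected TILDs keep a
    minimum separation, so one detection legitimately covers a burst —
    one-to-one matching would systematically under-count those events.
    """
    detected = np.asarray(detected_frames, dtype=float)
    true = np.asarray(true_frames, dtype=float)
    if len(true) == 0 or len(detected) == 0:
        return 0, 0
    hit_true = int(
        np.sum(np.min(np.abs(true[:, None] - detected[None, :]), axis=1) <= tol_frames)
    )
    hit_det = int(
        np.sum(np.min(np.abs(detected[:, None] - true[None, :]), axis=1) <= tol_frames)
    )
    return hit_true, hit_det


def match_hops(
    detected_frames: np.ndarray,
    true_frames: np.ndarray,
    tol_frames: int,
) -> int:
    """One-to-one greedy nearest matching of detections to true hops.

    Pairs within ``tol_frames`` are matched closest-first; returns the
    number of matched pairs (detectability = matches / true hops,
    accuracy = matches / detections)."""
    detected = np.asarray(detected_frames)
    true = np.asarray(true_frames)
    if len(detected) == 0 or len(true) == 0:
        return 0
    pairs = [
        (abs(int(d) - int(t)), i, j)
        for i, d in enumerate(detected)
        for j, t in enumerate(true)
        if abs(int(d) - int(t)) <= tol_frames
    ]
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = 0
    for _, i, j in pairs:
        if i not in used_d and j not in used_t:
            used_d.add(i)
            used_t.add(j)
            matches += 1
    return matches
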