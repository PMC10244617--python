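"""MSD curves, motional-mode classification, and diffusion-model fitting.

The time-averaged per-dimension mean-square displacement of an N-frame
trajectory at lag n*dt is

    MSD_x(n dt) = 1/(N-1-n) * sum_{j=1}^{N-1-n} [x((j+n) dt) - x(j dt)]^2

(and likewise for y); the 2-D MSD is their sum.  The printed normalizer
N-1-n (one fewer pair than the natural N-n) is implemented verbatim; the
all-pairs variant is available behind ``all_pairs=True``.

On top of the MSD curve the module provides:

* the short-term diffusion coefficient D_2-4 (slope of the 2nd-4th MSD
  points / 4) and the y-intercept of that line, interpreted as 4*sigma_xy^2
  where sigma_xy is the localization precision;
* the relative-deviation statistic RD(N, n) = MSD(n dt) / (4 D_2-4 n dt)
  used to classify trajectories into suppressed / Brownian / directed
  motion against percentile thresholds from simulated Brownian nulls
  (the MSD offset is subtracted before forming the ratio, matching the
  4*sigma_xy^2 subtraction applied to all MSD plots; ``subtract_offset=False``
  gives the raw ratio);
* hop-diffusion and confined-diffusion MSD fits;
* the anomalous-diffusion exponent alpha from log(MSD/dt) vs log(dt).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .trajectory import Trajectory
from .units import NM2_PER_UM2, d_nm2s_to_um2s, d_um2s_to_nm2s


@dataclass
class MSDCurve:
    """Time-averaged MSD vs lag.  lags in s, msd values in nm^2."""

    lags: np.ndarray
    msd_x: np.ndarray
    msd_y: np.ndarray
    msd_2d: np.ndarray
    n_pairs: np.ndarray
    frame_time: float

    def __len__(self) -> int:
        return len(self.lags)


@dataclass
class ShortTermFit:
    """OLS line through the 2nd-4th MSD points.

    d_2_4 is in um^2/s, offset in nm^2.  sigma_xy = sqrt(offset/4) is the
    implied per-coordinate localization precision; it is None when the
    fitted offset is negative (noisy input), in which case the offset is
    retained for inspection.
    """

    d_2_4: float
    offset: float
    sigma_xy: float | None


@dataclass
class RDThresholds:
    """Empirical 2.5 / 97.5 percentile bounds of the Brownian-null RD."""

    rd_min: float
    rd_max: float
    N: int
    n: int
    frame_time: float
    n_sim: int


@dataclass
class HopFit:
    """Hop-diffusion MSD fit: d_micro, d_macro in um^2/s, L in nm."""

    d_micro: float
    d_macro: float
    L: float
    tau_c: float
    residual: float
    converged: bool


@dataclass
class ConfinedFit:
    """Confined-diffusion MSD fit: L in nm, d_micro in um^2/s."""

    L: float
    d_micro: float
    residual: float
    converged: bool


@dataclass
class AnomalyCurve:
    """Pooled log10(MSD/dt) vs log10(dt) and the fitted exponent alpha."""

    log_dt: np.ndarray
    log_msd_over_dt: np.ndarray
    alpha: float
    C: float


def compute_msd(
    traj: Trajectory, max_lag_frames: int, all_pairs: bool = False
) -> MSDCurve:
    """Time-averaged MSD up to max_lag_frames.

    Default indexing follows the printed formula (normalizer N-1-n, i.e.
    the pair ending at the final frame is dropped); ``all_pairs=True`` uses
    all N-n start points instead.
    """
    N = traj.n_frames
    if not 1 <= max_lag_frames <= N - 2:
        raise ValueError(f"max_lag_frames must be in [1, {N - 2}]")
    x, y = traj.x, traj.y
    lags = np.arange(1, max_lag_frames + 1)
    msd_x = np.empty(max_lag_frames)
    msd_y = np.empty(max_lag_frames)
    n_pairs = np.empty(max_lag_frames, dtype=np.int64)
    for i, n in enumerate(lags):
        m = (N - n) if all_pairs else (N - 1 - n)
        dx = x[n : n + m] - x[:m]
        dy = y[n : n + m] - y[:m]
        msd_x[i] = np.mean(dx * dx)
        msd_y[i] = np.mean(dy * dy)
        n_pairs[i] = m
    return MSDCurve(
        lags=lags * traj.frame_time,
        msd_x=msd_x,
        msd_y=msd_y,
        msd_2d=msd_x + msd_y,
        n_pairs=n_pairs,
        frame_time=traj.frame_time,
    )


def estimate_short_term(msd: MSDCurve) -> ShortTermFit:
    """D_2-4 and the MSD offset from the 2nd, 3rd and 4th lag points."""
    if len(msd) < 4:
        raise ValueError("need at least 4 MSD lags for the 2-4-point fit")
    t = msd.lags[1:4]
    v = msd.msd_2d[1:4]
    slope, intercept = np.polyfit(t, v, 1)  # nm^2/s, nm^2
    d = d_nm2s_to_um2s(slope / 4.0)
    sigma = math.sqrt(intercept / 4.0) if intercept >= 0 else None
    return ShortTermFit(d_2_4=d, offset=float(intercept), sigma_xy=sigma)


def rd_statistic(
    traj: Trajectory,
    n: int,
    short_term: ShortTermFit | None = None,
    subtract_offset: bool = True,
) -> float:
    """RD(N, n): the MSD at lag n relative to the short-term extrapolation.

    The 2-4-point intercept (the 4*sigma_xy^2 offset) is subtracted from the
    numerator by default, so the statistic measures pure diffusional
    deviation; pass subtract_offset=False for the raw ratio.  Returns NaN
    (unclassifiable) when D_2-4 <= 0.
    """
    msd = compute_msd(traj, max_lag_frames=max(n, 4))
    if short_term is None:
        short_term = estimate_short_term(msd)
    if short_term.d_2_4 <= 0:
        return float("nan")
    numerator = msd.msd_2d[n - 1]
    if subtract_offset:
        numerator = numerator - short_term.offset
    denom = 4.0 * d_um2s_to_nm2s(short_term.d_2_4) * n * traj.frame_time
    return float(numerator / denom)


def rd_null_thresholds(
    N: int,
    n: int,
    frame_time: float,
    n_sim: int = 5000,
    seed: int = 0,
    loc_error_sd: float = 0.0,
    subtract_offset: bool = True,
) -> RDThresholds:
    """2.5 / 97.5 percentile RD bounds from simulated Brownian nulls.

    The nulls are noise-free by default, which makes the statistic
    scale-free (any D > 0 gives the same distribution); localization noise
    can be added for sensitivity checks, in which case the null does depend
    on D and the fixed reference D = 1 um^2/s is used.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for stable percentiles")
    from .simulate import add_localization_noise, simulate_brownian_trajectory

    values = np.empty(n_sim)
    for i in range(n_sim):
        traj = simulate_brownian_trajectory(1.0, N, frame_time, seed=seed, traj_id=i)
        if loc_error_sd > 0:
            traj = add_localization_noise(traj, loc_error_sd, seed=seed + 1, traj_id=i)
        values[i] = rd_statistic(traj, n, subtract_offset=subtract_offset)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return RDThresholds(
        rd_min=float(lo), rd_max=float(hi), N=N, n=n, frame_time=frame_time, n_sim=n_sim
    )


def classify_mode(
    traj: Trajectory,
    thresholds: RDThresholds,
    subtract_offset: bool = True,
    degenerate_policy: str = "unclassifiable",
) -> str:
    """Classify a trajectory as 'suppressed', 'brownian' or 'directed'.

    Strict comparisons against the null percentiles; ties fall to
    'brownian'.  ``degenerate_policy`` decides what happens when the RD is
    undefined because the short-term slope is non-positive:
    'unclassifiable' reports the flag, 'suppressed' assigns the suppressed
    mode on the grounds that a non-positive short-term MSD slope means the
    motion is unresolvable beneath the localization noise — maximally
    inconsistent with free diffusion (a Brownian trajectory essentially
    never produces one at these pair counts).
    """
    if degenerate_policy not in ("unclassifiable", "suppressed"):
        raise ValueError("degenerate_policy must be 'unclassifiable' or 'suppressed'")
    if traj.n_frames != thresholds.N:
        raise ValueError(
            f"trajectory has {traj.n_frames} frames but thresholds were "
            f"computed for N={thresholds.N}"
        )
    rd = rd_statistic(traj, thresholds.n, subtract_offset=subtract_offset)
    if math.isnan(rd):
        return degenerate_policy
    if rd < thresholds.rd_min:
        return "suppressed"
    if rd > thresholds.rd_max:
        return "directed"
    return "brownian"


def hop_msd_model(t: np.ndarray, d_micro: float, d_macro: float, L: float) -> np.ndarray:
    """2-D hop-diffusion MSD (nm^2): (L^2/3)(1 - exp(-t/tau_c)) + 4 D_MACRO t
    with tau_c = L^2 / (12 (D_micro - D_MACRO)).

    Slope 4*D_micro at t->0 and 4*D_MACRO at t->infinity; the confinement
    term contributes the L^2/3 plateau.  d in um^2/s, L in nm, t in s.
    """
    dm = d_um2s_to_nm2s(d_micro)
    dM = d_um2s_to_nm2s(d_macro)
    tau_c = L * L / (12.0 * (dm - dM))
    return (L * L / 3.0) * (1.0 - np.exp(-t / tau_c)) + 4.0 * dM * t


def confined_msd_model(
    t: np.ndarray, L: float, d_micro: float, k_max: int = 99
) -> np.ndarray:
    """2-D confined-diffusion MSD (nm^2) for free diffusion in an L x L box:

        MSD_x(t) = (L^2/6) [1 - (96/pi^4) sum_{k odd} k^-4
                                exp(-(k pi / L)^2 D t)]

    summed over x and y.  The series is truncated once the next term falls
    below 1e-10 of the plateau (hard cap k <= k_max).
    """
    t = np.asarray(t, dtype=np.float64)
    d = d_um2s_to_nm2s(d_micro)
    plateau_x = L * L / 6.0
    series = np.zeros_like(t)
    prefac = 96.0 / math.pi**4
    for k in range(1, k_max + 1, 2):
        term = (1.0 / k**4) * np.exp(-((k * math.pi / L) ** 2) * d * t)
        series += term
        if np.max(term) * prefac < 1e-10:
            break
    msd_x = plateau_x * (1.0 - prefac * series)
    return 2.0 * msd_x


def _msd_fit_arrays(
    msd: MSDCurve,
    fit_range: tuple[int, int] | None,
    subtract_offset: bool | float,
) -> tuple[np.ndarray, np.ndarray, ShortTermFit]:
    """subtract_offset: False = raw curve; True = subtract the fitted
    2-4-point intercept; a float = subtract that constant (nm^2), e.g. the
    known 4*sigma_xy^2 when the localization error is known — preferable
    for confined/hop motion, whose curvature inflates the fitted
    intercept beyond the pure noise offset."""
    st = estimate_short_term(msd)
    lo, hi = (1, len(msd)) if fit_range is None else fit_range
    t = msd.lags[lo - 1 : hi]
    v = msd.msd_2d[lo - 1 : hi].copy()
    if subtract_offset is True:
        v -= st.offset
    elif subtract_offset is not False:
        v -= float(subtract_offset)
    return t, v, st


def fit_hop_diffusion(
    msd: MSDCurve,
    fit_range: tuple[int, int] | None = None,
    subtract_offset: bool | float = False,
    weighted: bool = False,
) -> HopFit:
    """Fit the hop-diffusion MSD model by trust-region least squares.

    Free parameters D_micro, D_MACRO, L with D_micro > D_MACRO >= 0 and
    L > 0 enforced via the parametrization (D_MACRO, dD = D_micro-D_MACRO, L).
    Initialization: D_micro from the 2-4-point slope, D_MACRO from the
    last-quarter slope, L from the mid-curve plateau estimate.  A fit where
    D_micro and D_MACRO collapse within tolerance, or that fails to
    converge, is flagged unfittable (converged=False).
    """
    t, v, st = _msd_fit_arrays(msd, fit_range, subtract_offset)
    if len(t) < 4:
        raise ValueError("need at least 4 MSD points to fit")
    w = np.sqrt(msd.n_pairs[: len(v)].astype(float)) if weighted else np.ones(len(v))

    # initialization
    d_micro0 = max(st.d_2_4, 1e-6)
    q = max(len(t) // 4, 2)
    slope_end = np.polyfit(t[-q:], v[-q:], 1)[0]
    d_macro0 = min(max(d_nm2s_to_um2s(slope_end / 4.0), 1e-6), 0.9 * d_micro0)
    mid = len(t) // 2
    plateau_est = v[mid] - 4.0 * d_um2s_to_nm2s(d_macro0) * t[mid]
    L0 = math.sqrt(3.0 * plateau_est) if plateau_est > 0 else 100.0

    def resid(p):
        d_macro, dd, L = p
        return (hop_msd_model(t, d_macro + dd, d_macro, L) - v) * w

    try:
        sol = least_squares(
            resid,
            x0=[d_macro0, max(d_micro0 - d_macro0, 1e-3), L0],
            bounds=([0.0, 1e-9, 1e-3], [np.inf, np.inf, np.inf]),
            method="trf",
        )
    except Exception:
        return HopFit(float("nan"), float("nan"), float("nan"), float("nan"),
                      float("inf"), False)
    d_macro, dd, L = sol.x
    d_micro = d_macro + dd
    tau_c = L * L / (12.0 * d_um2s_to_nm2s(dd))
    converged = bool(sol.success) and dd > 1e-6 * max(d_micro, 1.0)
    residual = float(np.sqrt(np.mean((sol.fun / w) ** 2)))
    return HopFit(
        d_micro=float(d_micro),
        d_macro=float(d_macro),
        L=float(L),
        tau_c=float(tau_c),
        residual=residual,
        converged=converged,
    )


def fit_confined_diffusion(
    msd: MSDCurve,
    fit_range: tuple[int, int] | None = None,
    subtract_offset: bool | float = False,
) -> ConfinedFit:
    """Fit the confined-diffusion (closed box) MSD model; free L, D_micro."""
    t, v, st = _msd_fit_arrays(msd, fit_range, subtract_offset)
    if len(t) < 3:
        raise ValueError("need at least 3 MSD points to fit")
    plateau = max(float(np.max(v)), 1.0)
    L0 = math.sqrt(3.0 * plateau)
    d0 = max(st.d_2_4, 1e-6)

    def resid(p):
        L, d = p
        return confined_msd_model(t, L, d) - v

    try:
        sol = least_squares(resid, x0=[L0, d0], bounds=([1e-3, 1e-9], [np.inf, np.inf]),
                            method="trf")
    except Exception:
        return ConfinedFit(float("nan"), float("nan"), float("inf"), False)
    residual = float(np.sqrt(np.mean(sol.fun**2)))
    return ConfinedFit(
        L=float(sol.x[0]), d_micro=float(sol.x[1]), residual=residual,
        converged=bool(sol.success),
    )


def anomaly_curve(
    msd_curves: list[MSDCurve],
    fit_window: tuple[float, float] | None = None,
    subtract_offset: bool = False,
) -> AnomalyCurve:
    """Pool log10(MSD/dt) vs log10(dt) across frame rates and fit alpha.

    For MSD = C * dt^alpha, log(MSD/dt) = log C + (alpha-1) log dt, so the
    OLS slope over ``fit_window`` (a lag-time interval in s; default all
    points) plus one is the anomalous-diffusion exponent.
    """
    log_dt, log_ratio = [], []
    for curve in msd_curves:
        v = curve.msd_2d.copy()
        if subtract_offset:
            v -= estimate_short_term(curve).offset
        ok = v > 0
        log_dt.append(np.log10(curve.lags[ok]))
        log_ratio.append(np.log10(v[ok] / curve.lags[ok]))
    log_dt = np.concatenate(log_dt)
    log_ratio = np.concatenate(log_ratio)
    order = np.argsort(log_dt)
    log_dt, log_ratio = log_dt[order], log_ratio[order]
    if fit_window is None:
        sel = np.ones_like(log_dt, dtype=bool)
    else:
        sel = (log_dt >= math.log10(fit_window[0])) & (
            log_dt <= math.log10(fit_window[1])
        )
    if not np.any(sel):
        raise ValueError("fit_window selects no points")
    slope, intercept = np.polyfit(log_dt[sel], log_ratio[sel], 1)
    return AnomalyCurve(
        log_dt=log_dt,
        log_msd_over_dt=log_ratio,
        alpha=float(slope + 1.0),
        C=float(10.0**intercept),
    )


def ensemble_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Average MSD curves over an ensemble (curves must share their lags)."""
    n = min(len(c) for c in curves)
    lags = curves[0].lags[:n]
    for c in curves:
        if not np.allclose(c.lags[:n], lags):
            raise ValueError("curves have incompatible lag grids")
    msd_x = np.mean([c.msd_x[:n] for c in curves], axis=0)
    msd_y = np.mean([c.msd_y[:n] for c in curves], axis=0)
    n_pairs = np.sum([c.n_pairs[:n] for c in curves], axis=0)
    return MSDCurve(
        lags=lags, msd_x=msd_x, msd_y=msd_y, msd_2d=msd_x + msd_y,
        n_pairs=n_pairs, frame_time=curves[0].frame_time,
    )
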