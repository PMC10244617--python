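"""Monte Carlo simulation of hop diffusion on a permeable-barrier lattice.

The plasma membrane is modelled as a two-dimensional square lattice of
partially permeable barriers (compartment side ``L``).  A molecule performs
free Brownian motion with coefficient ``d_micro`` in micro-steps of duration
``micro_step``; whenever a proposed micro-step would carry it across a
barrier line (an integer multiple of ``L`` on either axis, with a random
lattice offset per trajectory), the crossing succeeds with probability
``p_cross`` (a hop) and otherwise the landing position is mirrored about the
barrier line.  Positions are recorded every ``frame_time`` seconds, and each
successful crossing is logged as a ground-truth hop event.

Localization noise is deliberately *not* added here — use
:func:`add_localization_noise` so the clean ground truth stays available.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory
from .units import d_um2s_to_nm2s

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class HopSimConfig:
    """Parameters of the hop-diffusion simulation.

    Attributes
    ----------
    d_micro : float
        Diffusion coefficient inside a compartment (um^2/s).
    L : float
        Compartment side length (nm).
    p_cross : float
        Transmission probability per barrier-crossing attempt.
    micro_step : float
        Simulation time step (s).  One attempt = one micro-step whose
        proposed displacement crosses a barrier.
    frame_time : float
        Recording interval (s); must be an integer multiple of micro_step.
    n_frames : int
        Number of recorded frames per trajectory.
    loc_error_sd : float
        Per-coordinate Gaussian localization error (nm); stored for study
        configuration, applied separately via add_localization_noise.
    seed : int
        PRNG seed; per-trajectory sub-streams are derived from
        (seed, trajectory index).
    """

    d_micro: float
    L: float
    p_cross: float
    frame_time: float
    n_frames: int
    micro_step: float = 1e-7
    loc_error_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_micro <= 0:
            raise ValueError("d_micro must be > 0")
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if not 0.0 <= self.p_cross <= 1.0:
            raise ValueError("p_cross must be in [0, 1]")
        if self.loc_error_sd < 0:
            raise ValueError("loc_error_sd must be >= 0")
        ratio = self.frame_time / self.micro_step
        if abs(ratio - round(ratio)) > 1e-6:
            raise ValueError(
                "frame_time must be an integer multiple of micro_step "
                f"(got ratio {ratio})"
            )
        step_sd = math.sqrt(2.0 * d_um2s_to_nm2s(self.d_micro) * self.micro_step)
        if step_sd > self.L / 4.0:
            warnings.warn(
                f"micro-step SD {step_sd:.1f} nm exceeds L/4 = {self.L / 4:.1f} nm; "
                "barrier bookkeeping may be unreliable",
                stacklevel=2,
            )

    @property
    def steps_per_frame(self) -> int:
        return round(self.frame_time / self.micro_step)


@dataclass
class SimulatedTrajectory:
    """A simulated trajectory plus its ground truth.

    ``hop_times`` / ``hop_frames`` / ``hop_axes`` / ``hop_dirs`` describe the
    successful barrier crossings: the crossing time (s), the recorded frame
    whose interval contains the crossing, the axis (0=x, 1=y), and the
    direction (+1/-1 compartment index change on that axis).
    ``compartment_ids`` holds the per-frame integer lattice coordinates of
    the occupied compartment.
    """

    trajectory: Trajectory
    hop_times: np.ndarray
    hop_frames: np.ndarray
    hop_axes: np.ndarray
    hop_dirs: np.ndarray
    compartment_ids: np.ndarray
    lattice_offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def hop_events(self) -> list[tuple[float, int, int]]:
        """Hop events as (time s, frame index, axis) tuples."""
        return [
            (float(t), int(f), int(a))
            for t, f, a in zip(self.hop_times, self.hop_frames, self.hop_axes)
        ]

    @property
    def n_hops(self) -> int:
        return len(self.hop_times)


@njit(cache=True)
def _hop_kernel(normals, uniforms, L, p_cross, ox, oy, spf, n_frames):
    """Sequential barrier walk.  normals/uniforms are (n_steps, 2) arrays;
    the uniform at (step, axis) is consumed only when that micro-step
    proposes a crossing, so the draw pattern is reproducible."""
    n_steps = spf * (n_frames - 1)
    pos = np.empty((n_frames, 2), dtype=np.float64)
    cap = 2 * n_steps
    hop_steps = np.empty(cap, dtype=np.int64)
    hop_axes = np.empty(cap, dtype=np.int8)
    hop_dirs = np.empty(cap, dtype=np.int8)
    n_hops = 0

    xy = np.zeros(2, dtype=np.float64)
    off = np.empty(2, dtype=np.float64)
    off[0] = ox
    off[1] = oy
    pos[0, 0] = 0.0
    pos[0, 1] = 0.0
    for s in range(n_steps):
        for axis in range(2):
            cur = xy[axis]
            new = cur + normals[s, axis]
            k_cur = math.floor((cur - off[axis]) / L)
            k_new = math.floor((new - off[axis]) / L)
            if k_new != k_cur:
                # one barrier per axis per micro-step: the one adjacent to
                # the current compartment in the direction of motion
                if k_new > k_cur:
                    barrier = off[axis] + (k_cur + 1) * L
                    direction = 1
                else:
                    barrier = off[axis] + k_cur * L
                    direction = -1
                if uniforms[s, axis] < p_cross:
                    xy[axis] = new  # hop succeeds
                    hop_steps[n_hops] = s
                    hop_axes[n_hops] = axis
                    hop_dirs[n_hops] = direction
                    n_hops += 1
                else:
                    xy[axis] = 2.0 * barrier - new  # reflect
            else:
                xy[axis] = new
        if (s + 1) % spf == 0:
            f = (s + 1) // spf
            pos[f, 0] = xy[0]
            pos[f, 1] = xy[1]
    return pos, hop_steps[:n_hops], hop_axes[:n_hops], hop_dirs[:n_hops]


def _hop_reference(normals, uniforms, L, p_cross, ox, oy, spf, n_frames):
    """Pure-Python mirror of _hop_kernel; the unit-test oracle at tiny n."""
    n_steps = spf * (n_frames - 1)
    pos = np.empty((n_frames, 2))
    pos[0] = 0.0
    xy = [0.0, 0.0]
    off = [ox, oy]
    steps, axes, dirs = [], [], []
    for s in range(n_steps):
        for axis in range(2):
            cur = xy[axis]
            new = cur + normals[s, axis]
            k_cur = math.floor((cur - off[axis]) / L)
            k_new = math.floor((new - off[axis]) / L)
            if k_new != k_cur:
                if k_new > k_cur:
                    barrier = off[axis] + (k_cur + 1) * L
                    direction = 1
                else:
                    barrier = off[axis] + k_cur * L
                    direction = -1
                if uniforms[s, axis] < p_cross:
                    xy[axis] = new
                    steps.append(s)
                    axes.append(axis)
                    dirs.append(direction)
                else:
                    xy[axis] = 2.0 * barrier - new
            else:
                xy[axis] = new
        if (s + 1) % spf == 0:
            pos[(s + 1) // spf] = xy
    return (
        pos,
        np.array(steps, dtype=np.int64),
        np.array(axes, dtype=np.int8),
        np.array(dirs, dtype=np.int8),
    )


def simulate_hop_trajectory(
    config: HopSimConfig, traj_id: int = 0
) -> SimulatedTrajectory:
    """Simulate one hop-diffusion trajectory with ground-truth hop events.

    The lattice origin is offset by a uniform random shift in [0, L)^2 per
    trajectory, and the walker starts at the coordinate origin.
    """
    rng = np.random.default_rng([config.seed, traj_id])
    spf = config.steps_per_frame
    n_steps = spf * (config.n_frames - 1)
    step_sd = math.sqrt(2.0 * d_um2s_to_nm2s(config.d_micro) * config.micro_step)
    offset = rng.uniform(0.0, config.L, size=2)
    normals = rng.standard_normal((n_steps, 2)) * step_sd
    uniforms = rng.random((n_steps, 2))

    kernel = _hop_kernel if _HAVE_NUMBA else _hop_reference
    pos, hop_steps, hop_axes, hop_dirs = kernel(
        normals,
        uniforms,
        float(config.L),
        float(config.p_cross),
        float(offset[0]),
        float(offset[1]),
        spf,
        config.n_frames,
    )
    hop_times = (hop_steps + 1) * config.micro_step
    hop_frames = np.minimum(
        np.floor(hop_times / config.frame_time).astype(np.int64),
        config.n_frames - 1,
    )
    compartment_ids = np.floor((pos - offset[None, :]) / config.L).astype(np.int64)
    traj = Trajectory(pos, config.frame_time, id=traj_id)
    return SimulatedTrajectory(
        trajectory=traj,
        hop_times=hop_times,
        hop_frames=hop_frames,
        hop_axes=hop_axes.astype(np.int64),
        hop_dirs=hop_dirs.astype(np.int64),
        compartment_ids=compartment_ids,
        lattice_offset=offset,
    )


def simulate_hop_ensemble(
    config: HopSimConfig, n_trajectories: int
) -> list[SimulatedTrajectory]:
    """Simulate an ensemble; trajectory i uses the sub-stream (seed, i)."""
    return [simulate_hop_trajectory(config, traj_id=i) for i in range(n_trajectories)]


def simulate_brownian_trajectory(
    d: float,
    n_frames: int,
    frame_time: float,
    seed: int = 0,
    traj_id: int = 0,
) -> Trajectory:
    """Simple Brownian trajectory: per-axis Gaussian frame displacements of
    variance 2*d*frame_time (d in um^2/s, positions in nm)."""
    if d < 0:
        raise ValueError("d must be >= 0")
    rng = np.random.default_rng([seed, traj_id])
    sd = math.sqrt(2.0 * d_um2s_to_nm2s(d) * frame_time)
    steps = rng.standard_normal((n_frames - 1, 2)) * sd
    pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return Trajectory(pos, frame_time, id=traj_id)


def add_localization_noise(
    traj: Trajectory, sigma_nm: float, seed: int = 0, traj_id: int | None = None
) -> Trajectory:
    """Return a copy with i.i.d. Gaussian noise of SD sigma_nm added to every
    coordinate.  The input trajectory is left unmodified."""
    if sigma_nm < 0:
        raise ValueError("sigma_nm must be >= 0")
    if sigma_nm == 0:
        return Trajectory(traj.positions.copy(), traj.frame_time, traj.id)
    tid = traj.id if traj_id is None else traj_id
    rng = np.random.default_rng([seed, int(tid) if not isinstance(tid, int) else tid])
    noisy = traj.positions + rng.standard_normal(traj.positions.shape) * sigma_nm
    return Trajectory(noisy, traj.frame_time, traj.id)


def true_residencies(
    sim: SimulatedTrajectory, min_duration_s: float = 0.0
) -> np.ndarray:
    """Ground-truth residency durations (s) between consecutive hop events.

    The censored first (start -> first hop) and last (last hop -> end)
    intervals are excluded; durations below ``min_duration_s`` are dropped.
    """
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be >= 0")
    if sim.n_hops < 2:
        return np.empty(0)
    durations = np.diff(sim.hop_times)
    return durations[durations >= min_duration_s]
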