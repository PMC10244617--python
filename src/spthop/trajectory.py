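"""The Trajectory container: time-ordered 2-D positions at a fixed frame time.

All analysis in this package operates on this one type.  Positions are in
nanometres; the frame time ``frame_time`` is in seconds.  Frames are
contiguous — a detection gap splits a recording into separate trajectories
rather than being interpolated.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """A single-molecule trajectory.

    Parameters
    ----------
    positions : (N, 2) float array
        x, y coordinates in nm, one row per frame.
    frame_time : float
        Recording interval (s).
    id : int | str
        Track identifier.
    """

    positions: np.ndarray
    frame_time: float
    id: int | str = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")
        if self.n_frames < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_time

    def reversed(self) -> "Trajectory":
        """Time-reversed copy (used by retrograde TILD analysis)."""
        return Trajectory(self.positions[::-1].copy(), self.frame_time, self.id)
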