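"""Shared file I/O: the trajectory CSV dialect and report serialization.

One CSV dialect is used by every module: columns ``track_id, frame, x_nm,
y_nm`` with a header row, UTF-8, 0-based frames, coordinates serialized at
0.01-nm precision.  Ground-truth hop events use ``track_id, frame, time_s,
axis``; MSD curves use ``lag_s, msd_x_nm2, msd_y_nm2, msd_2d_nm2, n_pairs``.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .msd import MSDCurve
from .simulate import SimulatedTrajectory
from .trajectory import Trajectory

TRAJECTORY_COLUMNS = ["track_id", "frame", "x_nm", "y_nm"]


def write_trajectories(trajs: list[Trajectory], path: str | Path) -> None:
    """Write trajectories in the shared CSV dialect, ordered (track, frame)."""
    rows = []
    for tr in trajs:
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tr.id,
                    "frame": np.arange(tr.n_frames),
                    "x_nm": np.round(tr.x, 2),
                    "y_nm": np.round(tr.y, 2),
                }
            )
        )
    if rows:
        df = pd.concat(rows, ignore_index=True)
        df = df.sort_values(["track_id", "frame"], kind="stable")
    else:
        df = pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    df.to_csv(path, index=False)


def read_trajectories(path: str | Path, frame_time: float) -> list[Trajectory]:
    """Read the shared trajectory CSV; rows are grouped by track_id and
    frame-sorted.  Malformed rows and duplicate (track, frame) pairs raise
    with the offending line numbers."""
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {missing}")
    bad = df[df[["frame", "x_nm", "y_nm"]].isna().any(axis=1)]
    if len(bad):
        lines = (bad.index + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"malformed rows at lines {lines}")
    dup = df.duplicated(subset=["track_id", "frame"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"duplicate (track_id, frame) rows at lines {lines}")
    out = []
    for tid, group in df.groupby("track_id", sort=True):
        g = group.sort_values("frame")
        frames = g["frame"].to_numpy()
        if np.any(np.diff(frames) != 1):
            raise ValueError(f"track {tid} has non-contiguous frames")
        out.append(
            Trajectory(g[["x_nm", "y_nm"]].to_numpy(float), frame_time, id=tid)
        )
    return out


def write_hop_events(sims: list[SimulatedTrajectory], path: str | Path) -> None:
    """Ground-truth hop events CSV: track_id, frame, time_s, axis."""
    rows = []
    for sim in sims:
        rows.append(
            pd.DataFrame(
                {
                    "track_id": sim.trajectory.id,
                    "frame": sim.hop_frames,
                    "time_s": sim.hop_times,
                    "axis": sim.hop_axes,
                }
            )
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["track_id", "frame", "time_s", "axis"])
    )
    df.to_csv(path, index=False)


def write_msd_curve(curve: MSDCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "lag_s": curve.lags,
            "msd_x_nm2": curve.msd_x,
            "msd_y_nm2": curve.msd_y,
            "msd_2d_nm2": curve.msd_2d,
            "n_pairs": curve.n_pairs,
        }
    ).to_csv(path, index=False)


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
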