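"""Shared in-memory containers: movies, trajectories, cells.

Tabular data uses the quot-style CSV dialect throughout: pixel coordinates
``y, x`` (pixel-center convention, 0-based), micron coordinates
``y_um, x_um``, a ``frame`` index, and a ``trajectory`` id once linked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Movie", "Trajectory", "CellRecord", "trajectories_from_table"]


@dataclass
class Movie:
    """Time-ordered stack of camera frames with acquisition metadata."""

    frames: np.ndarray  # (T, H, W) camera counts
    dt: float  # frame interval (s)
    pixel_size: float  # um per pixel
    channel: str = ""

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if np.any(np.asarray(self.frames) < 0):
            raise ValueError("camera counts must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class Trajectory:
    """Time-ordered localizations of one molecule within one cell."""

    trajectory_id: int
    cell_id: int
    frames: np.ndarray  # strictly increasing frame indices
    positions: np.ndarray  # (n, 2) [x_um, y_um]
    epoch: str | None = None  # optional PAPA epoch class

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape != (self.frames.size, 2):
            raise ValueError("positions must be (n, 2) matching frames")
        if self.frames.size > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def n_jumps(self) -> int:
        return max(len(self) - 1, 0)

    def jumps(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)


@dataclass
class CellRecord:
    """All trajectories of one cell plus per-cell metadata."""

    cell_id: int
    condition: str = ""
    trajectories: list[Trajectory] = field(default_factory=list)
    mean_intensity: float | None = None
    table: pd.DataFrame | None = None  # full localization/ground-truth table

    def __post_init__(self) -> None:
        for t in self.trajectories:
            if t.cell_id != self.cell_id:
                raise ValueError("trajectory cell_id mismatch")

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    def n_locs_per_frame(self) -> pd.Series:
        frames = np.concatenate([t.frames for t in self.trajectories]) \
            if self.trajectories else np.array([], dtype=int)
        return pd.Series(frames).value_counts().sort_index()

    def positions_list(self) -> list[np.ndarray]:
        """Per-trajectory (n, 2) position arrays with >= 1 jump."""
        return [t.positions for t in self.trajectories if len(t) >= 2]


def trajectories_from_table(
    table: pd.DataFrame, cell_id: int = 0
) -> list[Trajectory]:
    """Build Trajectory objects from a table with columns
    trajectory (or trajectory_id), frame, x_um, y_um [, epoch].

    Trajectory ids are only unique within a cell, so grouping includes
    cell_id when that column is present."""
    traj_col = "trajectory" if "trajectory" in table.columns else "trajectory_id"
    keys = ["cell_id", traj_col] if "cell_id" in table.columns else [traj_col]
    out = []
    for key, sub in table.groupby(keys, sort=True):
        tid = key[-1] if isinstance(key, tuple) else key
        sub = sub.sort_values("frame")
        epoch = None
        if "epoch" in sub.columns and sub["epoch"].notna().any():
            epoch = str(sub["epoch"].iloc[0])
        out.append(
            Trajectory(
                trajectory_id=int(tid),
                cell_id=int(sub["cell_id"].iloc[0]) if "cell_id" in sub.columns
                else cell_id,
                frames=sub["frame"].to_numpy(),
                positions=sub[["x_um", "y_um"]].to_numpy(),
                epoch=epoch,
            )
        )
    return out
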