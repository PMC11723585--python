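"""File I/O: 16-bit TIFF movies, quot-dialect CSV tables, JSON records."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .papa import IlluminationSequence
from .records import CellRecord, Movie
from .spectrum import FBoundEstimate, SpectrumPosterior

__all__ = [
    "save_movie",
    "load_movie",
    "save_locs",
    "load_locs",
    "save_trajectories",
    "load_trajectories",
    "save_spectrum",
    "save_fbound",
    "save_sequence",
    "load_sequence",
]


def save_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as multi-frame 16-bit grayscale TIFF."""
    frames = np.asarray(movie.frames)
    if frames.dtype != np.uint16:
        frames = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")


def load_movie(
    path: str | Path, dt: float = 0.00748, pixel_size: float = 0.16,
    channel: str = "",
) -> Movie:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return Movie(frames=frames, dt=dt, pixel_size=pixel_size, channel=channel)


def save_locs(locs: pd.DataFrame, path: str | Path) -> None:
    locs.to_csv(path, index=False)


def load_locs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_trajectories(
    cells: list[CellRecord] | pd.DataFrame,
    path: str | Path,
    pixel_size: float = 0.16,
) -> None:
    """Trajectory/ground-truth CSV with mirrored quot columns.

    Canonical columns cell_id, trajectory_id, frame, x_um, y_um (plus any
    ground-truth columns present) are mirrored into the quot dialect
    frame, y, x (pixels), trajectory.
    """
    if isinstance(cells, pd.DataFrame):
        table = cells.copy()
    else:
        table = pd.concat([c.table for c in cells], ignore_index=True)
    table["y"] = table["y_um"] / pixel_size
    table["x"] = table["x_um"] / pixel_size
    table["trajectory"] = table["trajectory_id"]
    table.to_csv(path, index=False)


def load_trajectories(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "trajectory" not in table.columns and "trajectory_id" in table.columns:
        table["trajectory"] = table["trajectory_id"]
    return table


def save_spectrum(spectrum: SpectrumPosterior, path: str | Path) -> None:
    """Spectrum CSV: one row per (D, sigma) state with its occupation."""
    D, S = spectrum.grid.state_arrays()
    pd.DataFrame(
        {"D": D, "sigma": S, "occupation": spectrum.occupations}
    ).to_csv(path, index=False)


def save_fbound(est: FBoundEstimate, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(est), fh, indent=2)


def save_sequence(seq: IlluminationSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "block_lengths": list(seq.block_lengths),
                "n_cycles": seq.n_cycles,
                "dt": seq.dt,
            },
            fh,
            indent=2,
        )


def load_sequence(path: str | Path) -> IlluminationSequence:
    with open(path) as fh:
        raw = json.load(fh)
    return IlluminationSequence(
        block_lengths=tuple(raw["block_lengths"]),
        n_cycles=int(raw["n_cycles"]),
        dt=float(raw.get("dt", 0.00748)),
    )
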