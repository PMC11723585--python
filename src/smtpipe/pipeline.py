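"""End-to-end drivers chaining the pipeline stages.

These are the compositions the analysis scripts and the acceptance tests
run: movie -> localizations -> trajectories -> spectrum -> f_bound, and the
simulation-based parameter-recovery experiment that validates the chain
against ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    DetectConfig,
    LocalizeConfig,
    OpticsConfig,
    SimulationConfig,
    SimState,
    TrackConfig,
)
from .detect import detect_and_localize_movie
from .records import CellRecord, Movie, trajectories_from_table
from .simulate import render_movie, simulate_trajectories
from .spectrum import DiffusionGrid
from .track import apply_qc, link
from .stats import pooled_fbound

__all__ = [
    "movie_to_trajectories",
    "cells_from_linked_tables",
    "fbound_from_cells",
    "recover_fbound_from_movies",
    "recover_fbound_from_trajectories",
]


def movie_to_trajectories(
    movie: Movie,
    dcfg: DetectConfig | None = None,
    lcfg: LocalizeConfig | None = None,
    tcfg: TrackConfig | None = None,
    max_density: int = 5,
):
    """Detect, localize, QC and link one movie.

    Returns (linked localization table, QC report).
    """
    dcfg = dcfg or DetectConfig()
    lcfg = lcfg or LocalizeConfig()
    tcfg = tcfg or TrackConfig(pixel_size=movie.pixel_size, dt=movie.dt)
    locs = detect_and_localize_movie(movie, dcfg, lcfg)
    locs, report = apply_qc(locs, start_frame=dcfg.start_frame,
                            max_density=max_density)
    linked = link(locs, tcfg)
    report.n_trajectories = int(linked["trajectory"].nunique()) \
        if len(linked) else 0
    return linked, report


def cells_from_linked_tables(tables: list[pd.DataFrame]) -> list[CellRecord]:
    """One CellRecord per linked localization table (one table per cell)."""
    cells = []
    for cid, table in enumerate(tables):
        t = table.copy()
        t["cell_id"] = cid
        cells.append(
            CellRecord(
                cell_id=cid,
                trajectories=trajectories_from_table(t, cell_id=cid),
                table=t,
            )
        )
    return cells


def fbound_from_cells(
    cells: list[CellRecord],
    grid: DiffusionGrid | None = None,
    threshold: float = 0.15,
):
    """Pooled defocalization-corrected f_bound (thin wrapper)."""
    return pooled_fbound(cells, grid, threshold=threshold)


def _two_state_config(
    true_fbound: float,
    D_bound: float = 0.02,
    D_free: float = 3.0,
    **overrides,
) -> SimulationConfig:
    states = [
        SimState(D=D_bound, occupancy=true_fbound, label="bound"),
        SimState(D=D_free, occupancy=1.0 - true_fbound, label="free"),
    ]
    return SimulationConfig(states=states, **overrides)


def recover_fbound_from_trajectories(
    true_fbound: float,
    seed: int = 0,
    grid: DiffusionGrid | None = None,
    **sim_overrides,
) -> dict:
    """Simulate ground-truth trajectories and re-estimate f_bound.

    Skips the imaging stages: the estimator sees the simulator's observed
    (noisy) positions directly. Returns truth, estimate and sizes.
    """
    cfg = _two_state_config(true_fbound, **sim_overrides)
    cells = simulate_trajectories(cfg, seed=seed)
    est = pooled_fbound(cells, grid)
    return {
        "true_fbound": true_fbound,
        "estimated_fbound": est.value,
        "error": est.value - true_fbound,
        "n_cells": len(cells),
        "n_trajectories": est.n_trajectories,
    }


def recover_fbound_from_movies(
    true_fbound: float,
    seed: int = 0,
    optics: OpticsConfig | None = None,
    grid: DiffusionGrid | None = None,
    **sim_overrides,
) -> dict:
    """Full-chain parameter recovery: simulate -> render -> detect ->
    localize -> track -> spectrum -> f_bound.

    Each simulated cell is rendered as its own 16-bit movie and processed
    with the standard settings. Returns truth, estimate, and bookkeeping
    (trajectory counts, QC flags).
    """
    optics = optics or OpticsConfig(clip_out_of_fov=True)
    cfg = _two_state_config(true_fbound, **sim_overrides)
    cells = simulate_trajectories(cfg, seed=seed)
    dcfg = DetectConfig()
    lcfg = LocalizeConfig(
        camera_gain=optics.camera_gain, camera_bg=optics.camera_bg,
    )
    tcfg = TrackConfig(pixel_size=optics.pixel_size, dt=cfg.dt)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    tables = []
    flagged = 0
    for cell in cells:
        movie = render_movie(
            [cell], optics, dt=cfg.dt, n_frames=cfg.n_frames,
            seed=int(rng.integers(2**31)),
        )
        linked, report = movie_to_trajectories(movie, dcfg, lcfg, tcfg)
        flagged += int(report.flagged)
        tables.append(linked)
    out_cells = cells_from_linked_tables(tables)
    est = pooled_fbound(out_cells, grid)
    return {
        "true_fbound": true_fbound,
        "estimated_fbound": est.value,
        "error": est.value - true_fbound,
        "n_cells": len(out_cells),
        "n_trajectories": est.n_trajectories,
        "n_flagged_movies": flagged,
    }
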