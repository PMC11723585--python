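import numpy as np
import pandas as pd
import pytest

from smtpipe.config import SimState, SimulationConfig
from smtpipe.records import CellRecord, Trajectory
from smtpipe.simulate import simulate_trajectories
from smtpipe.spectrum import DiffusionGrid


@pytest.fixture(scope="session")
def default_grid():
    return DiffusionGrid()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for fast unit tests (same span, fewer states)."""
    return DiffusionGrid(
        D_values=np.geomspace(0.01, 100, 30),
        sigma_values=np.array([0.025, 0.035, 0.045]),
    )


@pytest.fixture(scope="session")
def two_state_cells():
    """Small simulated cohort: 50/50 bound (D=0.02) / free (D=3)."""
    cfg = SimulationConfig(
        states=[
            SimState(D=0.02, occupancy=0.5, label="bound"),
            SimState(D=3.0, occupancy=0.5, label="free"),
        ],
        n_cells=5,
        traj_per_cell=200,
        seed=42,
    )
    return simulate_trajectories(cfg, seed=42)


def synthetic_trajectories(
    rng, n, n_jumps, D, sigma, dt=0.00748
):
    """Direct Brownian trajectories with localization error, fixed length
    (no slab/bleaching effects) — the clean substrate for likelihood tests."""
    out = []
    for _ in range(n):
        steps = rng.normal(0.0, np.sqrt(2 * D * dt), size=(n_jumps, 2))
        true = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        out.append(true + rng.normal(0.0, sigma, size=true.shape))
    return out


@pytest.fixture
def make_trajectories():
    return synthetic_trajectories


def cells_from_positions(groups):
    """CellRecords from lists of (n, 2) position arrays, one list per cell."""
    cells = []
    for cid, plist in enumerate(groups):
        trajs = [
            Trajectory(
                trajectory_id=i, cell_id=cid,
                frames=np.arange(p.shape[0]), positions=p,
            )
            for i, p in enumerate(plist)
        ]
        cells.append(CellRecord(cell_id=cid, trajectories=trajs))
    return cells


@pytest.fixture
def make_cells():
    return cells_from_positions
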