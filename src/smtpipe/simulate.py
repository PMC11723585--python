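"""Synthetic SMT data with the statistical structure the pipeline assumes.

Three generators:

* :func:`simulate_trajectories` — ground-truth trajectories from a mixture
  of diffusive states observed through a finite focal slab with Gaussian
  localization error and per-frame photobleaching;
* :func:`render_movie` — 16-bit EM-CCD movies of those trajectories
  (pixel-integrated Gaussian PSF, Poisson photons, gain, offset, read
  noise);
* :func:`simulate_papa_experiment` — a full proximity-assisted
  photoactivation experiment with interacting and non-interacting receiver
  subpopulations and the standard 5-cycle illumination sequence.

Every generator takes an explicit seed; identical seeds give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .config import OpticsConfig, PAPAConfig, SimulationConfig, SimState
from .papa import IlluminationSequence, EPOCH_LABELS
from .records import CellRecord, Movie, Trajectory

__all__ = [
    "simulate_trajectories",
    "render_movie",
    "simulate_papa_experiment",
    "PAPAExperiment",
]


def _draw_states(rng: np.random.Generator, states: list[SimState], n: int):
    occ = np.array([s.occupancy for s in states])
    return rng.choice(len(states), size=n, p=occ / occ.sum())


def _simulate_one(
    rng: np.random.Generator,
    D: float,
    sigma_loc: float,
    dt: float,
    focal_depth: float,
    bleach_prob: float,
    max_frames: int,
    x0: np.ndarray,
    z0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One molecule: returns (true_xy (n,2), observed_xy (n,2)), n >= 1.

    The molecule is recorded from its appearance frame until the first
    bleaching event or axial exit from the slab |z| <= focal_depth/2;
    re-entry is not re-linked (no gap closing).
    """
    half = focal_depth / 2.0
    # frames survived before bleaching (appearance frame always recorded)
    if bleach_prob > 0:
        n_bleach = int(rng.geometric(bleach_prob))
    else:
        n_bleach = max_frames
    n_max = min(n_bleach, max_frames)
    step_sd = np.sqrt(2.0 * D * dt)
    if n_max > 1 and step_sd > 0:
        dz = rng.normal(0.0, step_sd, size=n_max - 1)
        z = z0 + np.cumsum(dz)
        exited = np.flatnonzero(np.abs(z) > half)
        n_obs = int(exited[0]) + 1 if exited.size else n_max
    else:
        n_obs = 1 if step_sd > 0 or n_max >= 1 else n_max
        n_obs = min(max(n_obs, 1), n_max)
    steps = rng.normal(0.0, step_sd, size=(n_obs - 1, 2)) if n_obs > 1 \
        else np.zeros((0, 2))
    true_xy = np.vstack([x0, x0 + np.cumsum(steps, axis=0)]) if n_obs > 1 \
        else x0[None, :]
    noise = rng.normal(0.0, sigma_loc, size=true_xy.shape) if sigma_loc > 0 \
        else 0.0
    return true_xy, true_xy + noise


def simulate_trajectories(
    config: SimulationConfig, seed: int | None = None
) -> list[CellRecord]:
    """Ground-truth trajectory cohort: one CellRecord per simulated cell.

    Each molecule draws a diffusive state from the configured occupancies,
    appears at a uniformly random frame and position, performs 2D lateral
    plus hidden 1D axial Brownian steps of per-axis s.d. sqrt(2 D dt), and
    is observed (true position + Gaussian localization error) on frames
    where it lies inside the focal slab and has not yet bleached.

    The per-cell table keeps ground truth: true positions, state label and
    D, so downstream stages can be scored against the generator.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    state_D = np.array([s.D for s in config.states])
    state_label = [s.label or f"state{k}"
                   for k, s in enumerate(config.states)]
    half = config.focal_depth / 2.0
    cells = []
    for cell_id in range(config.n_cells):
        rows = []
        trajs = []
        states = _draw_states(rng, config.states, config.traj_per_cell)
        start_frames = rng.integers(0, config.n_frames, size=config.traj_per_cell)
        for tid in range(config.traj_per_cell):
            k = int(states[tid])
            x0 = rng.uniform(0.0, config.fov, size=2)
            z0 = rng.uniform(-half, half)
            f0 = int(start_frames[tid])
            max_frames = config.n_frames - f0
            if config.allow_switching and config.switch_rate > 0:
                true_xy, obs_xy, k_seq = _simulate_switching(
                    rng, config, k, x0, z0, max_frames
                )
            else:
                true_xy, obs_xy = _simulate_one(
                    rng, float(state_D[k]), config.sigma_loc, config.dt,
                    config.focal_depth, config.bleach_prob, max_frames, x0, z0,
                )
                k_seq = np.full(true_xy.shape[0], k)
            frames = f0 + np.arange(true_xy.shape[0])
            trajs.append(
                Trajectory(
                    trajectory_id=tid, cell_id=cell_id,
                    frames=frames, positions=obs_xy,
                )
            )
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_id,
                        "trajectory_id": tid,
                        "frame": frames,
                        "x_um": obs_xy[:, 0],
                        "y_um": obs_xy[:, 1],
                        "x_true": true_xy[:, 0],
                        "y_true": true_xy[:, 1],
                        "state_label": [state_label[j] for j in k_seq],
                        "state_D": state_D[k_seq],
                    }
                )
            )
        table = pd.concat(rows, ignore_index=True)
        cells.append(
            CellRecord(cell_id=cell_id, trajectories=trajs, table=table)
        )
    return cells


def _simulate_switching(rng, config, k0, x0, z0, max_frames):
    """Frame-by-frame simulation with per-frame state switching (optional)."""
    half = config.focal_depth / 2.0
    occ = np.array([s.occupancy for s in config.states])
    state_D = np.array([s.D for s in config.states])
    k = k0
    true_xy = [x0.copy()]
    k_seq = [k]
    z = z0
    for _ in range(max_frames - 1):
        if rng.random() < config.bleach_prob:
            break
        if rng.random() < config.switch_rate:
            k = int(rng.choice(len(occ), p=occ / occ.sum()))
        sd = np.sqrt(2.0 * state_D[k] * config.dt)
        z = z + rng.normal(0.0, sd)
        if abs(z) > half:
            break
        true_xy.append(true_xy[-1] + rng.normal(0.0, sd, size=2))
        k_seq.append(k)
    true_xy = np.asarray(true_xy)
    noise = rng.normal(0.0, config.sigma_loc, size=true_xy.shape) \
        if config.sigma_loc > 0 else 0.0
    return true_xy, true_xy + noise, np.asarray(k_seq)


def _integrated_psf_stamp(
    y_px: float, x_px: float, psf_sigma: float, radius: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel-integrated Gaussian around (y, x) in pixel-center convention.

    Pixel i spans [i - 0.5, i + 0.5]; returns (rows, cols, fractions).
    """
    iy, ix = int(round(y_px)), int(round(x_px))
    rows = np.arange(iy - radius, iy + radius + 1)
    cols = np.arange(ix - radius, ix + radius + 1)
    s = psf_sigma * np.sqrt(2.0)
    fy = 0.5 * (erf((rows + 0.5 - y_px) / s) - erf((rows - 0.5 - y_px) / s))
    fx = 0.5 * (erf((cols + 0.5 - x_px) / s) - erf((cols - 0.5 - x_px) / s))
    return rows, cols, np.outer(fy, fx)


def expected_photon_map(
    locs: pd.DataFrame,
    optics: OpticsConfig,
    n_frames: int | None = None,
    photon_col: str = "photons",
) -> np.ndarray:
    """Noise-free expected photons per pixel per frame for a localization
    table with columns frame, x_um, y_um and per-row photon counts."""
    H, W = optics.frame_shape
    T = int(locs["frame"].max()) + 1 if n_frames is None else n_frames
    lam = np.zeros((T, H, W))
    radius = int(np.ceil(4.0 * optics.psf_sigma)) + 1
    for frame, x_um, y_um, photons in zip(
        locs["frame"].to_numpy(),
        locs["x_um"].to_numpy(),
        locs["y_um"].to_numpy(),
        locs[photon_col].to_numpy(),
    ):
        y_px = y_um / optics.pixel_size
        x_px = x_um / optics.pixel_size
        rows, cols, frac = _integrated_psf_stamp(
            y_px, x_px, optics.psf_sigma, radius
        )
        rsel = (rows >= 0) & (rows < H)
        csel = (cols >= 0) & (cols < W)
        lam[int(frame)][np.ix_(rows[rsel], cols[csel])] += (
            photons * frac[np.ix_(rsel, csel)]
        )
    return lam


def render_movie(
    cells: list[CellRecord] | pd.DataFrame,
    optics: OpticsConfig,
    dt: float = 0.00748,
    n_frames: int | None = None,
    seed: int = 0,
    noise: bool = True,
) -> Movie:
    """Render localizations as a 16-bit EM-CCD movie.

    Each in-focus localization deposits a pixel-integrated 2D Gaussian
    scaled by a lognormal photon budget (median ``photons_median``); frame
    counts are ``camera_bg + camera_gain * Poisson(photons) + read noise``,
    clipped to unsigned 16 bits. With ``noise=False`` the noise-free
    expectation ``camera_bg + camera_gain * photons`` is returned unclipped
    at float precision (useful for oracle tests).

    Coordinates outside the field of view raise unless
    ``optics.clip_out_of_fov`` is set, in which case they are clipped to
    the frame edge.
    """
    rng = np.random.default_rng(seed)
    if isinstance(cells, pd.DataFrame):
        locs = cells.copy()
    else:
        locs = pd.concat([c.table for c in cells], ignore_index=True)
    H, W = optics.frame_shape
    xmax = W * optics.pixel_size
    ymax = H * optics.pixel_size
    oob = (
        (locs["x_um"] < 0) | (locs["x_um"] >= xmax)
        | (locs["y_um"] < 0) | (locs["y_um"] >= ymax)
    )
    if oob.any():
        if not optics.clip_out_of_fov:
            raise ValueError(
                f"{int(oob.sum())} localization(s) outside the field of view; "
                "set OpticsConfig.clip_out_of_fov to clip instead"
            )
        locs["x_um"] = locs["x_um"].clip(0, np.nextafter(xmax, 0))
        locs["y_um"] = locs["y_um"].clip(0, np.nextafter(ymax, 0))
    if "photons" not in locs.columns:
        locs["photons"] = np.exp(
            rng.normal(
                np.log(optics.photons_median),
                optics.photons_sigma_log,
                size=len(locs),
            )
        )
    lam = expected_photon_map(locs, optics, n_frames=n_frames)
    if noise:
        counts = optics.camera_bg + optics.camera_gain * rng.poisson(lam)
        if optics.read_noise > 0:
            counts = counts + rng.normal(0.0, optics.read_noise, size=lam.shape)
        frames = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    else:
        frames = optics.camera_bg + optics.camera_gain * lam
    return Movie(frames=frames, dt=dt, pixel_size=optics.pixel_size)


@dataclass
class PAPAExperiment:
    """Epoch-resolved PAPA trajectories with per-molecule ground truth.

    ``locs`` carries one row per localization with the recorded-frame index
    and ground-truth columns ``interacting`` (receiver bound to a sender)
    and ``route`` ('papa' or 'dr' reactivation). ``cell_truth`` counts
    reactivation events per cell and route.
    """

    locs: pd.DataFrame
    cell_truth: pd.DataFrame
    sequence: IlluminationSequence
    sim: SimulationConfig
    papa: PAPAConfig

    def cell_tables(self) -> list[pd.DataFrame]:
        return [sub.reset_index(drop=True)
                for _, sub in self.locs.groupby("cell_id", sort=True)]


def simulate_papa_experiment(
    sim: SimulationConfig, papa: PAPAConfig, seed: int | None = None
) -> PAPAExperiment:
    """Simulate a PAPA-SMT experiment.

    Receiver molecules (``sim.traj_per_cell`` per cell, ``sim.n_cells``
    cells) are split into interacting (sender-bound) and non-interacting
    classes with their own diffusive state mixtures. Each illumination
    cycle starts with all receivers dark (the 200-frame red bleach blocks
    re-darken any active molecule). After the green pulse a dark
    interacting receiver reactivates with ``p_papa_interacting`` and a
    non-interacting one with ``p_papa_background``; after the violet pulse
    any dark receiver reactivates with ``p_dr``. A reactivated molecule
    emits a trajectory in the imaging block that follows its pulse, with
    the same slab/bleaching kinematics as plain SMT simulation.
    """
    rng = np.random.default_rng(sim.seed if seed is None else seed)
    seq = IlluminationSequence(
        block_lengths=papa.block_lengths, n_cycles=papa.n_cycles, dt=sim.dt
    )
    block_len = seq.frames_per_block  # 30
    half = sim.focal_depth / 2.0
    rows = []
    truth_rows = []
    # pulse -> (route, recorded block index within cycle, reactivation probs)
    pulses = [("papa", 1), ("dr", 3)]
    for cell_id in range(sim.n_cells):
        lo, hi = papa.cell_size_range
        n_mol = max(1, int(round(sim.traj_per_cell * rng.uniform(lo, hi))))
        interacting = rng.random(n_mol) < papa.frac_interacting
        if papa.sender_pool is not None \
                and interacting.sum() > papa.sender_pool:
            # only sender_pool receivers find a sender to bind
            idx = rng.choice(np.flatnonzero(interacting),
                             size=papa.sender_pool, replace=False)
            interacting = np.zeros(n_mol, dtype=bool)
            interacting[idx] = True
        # draw each molecule's diffusive state from its class mixture
        state_idx = np.empty(n_mol, dtype=int)
        state_idx[interacting] = _draw_states(
            rng, papa.states_interacting, int(interacting.sum())
        )
        state_idx[~interacting] = _draw_states(
            rng, papa.states_free, int((~interacting).sum())
        )
        D_int = np.array([s.D for s in papa.states_interacting])
        D_free = np.array([s.D for s in papa.states_free])
        lbl_int = [s.label for s in papa.states_interacting]
        lbl_free = [s.label for s in papa.states_free]
        n_react = {"papa": 0, "dr": 0}
        tid = 0
        for cycle in range(papa.n_cycles):
            for route, rec_block in pulses:
                if route == "papa":
                    p = np.where(
                        interacting, papa.p_papa_interacting,
                        papa.p_papa_background,
                    )
                else:
                    p = np.full(n_mol, papa.p_dr)
                hit = np.flatnonzero(rng.random(n_mol) < p)
                n_react[route] += hit.size
                for m in hit:
                    D = float(D_int[state_idx[m]] if interacting[m]
                              else D_free[state_idx[m]])
                    label = (lbl_int[state_idx[m]] if interacting[m]
                             else lbl_free[state_idx[m]])
                    x0 = rng.uniform(0.0, sim.fov, size=2)
                    z0 = rng.uniform(-half, half)
                    _, obs = _simulate_one(
                        rng, D, sim.sigma_loc, sim.dt, sim.focal_depth,
                        sim.bleach_prob, block_len, x0, z0,
                    )
                    n_obs = obs.shape[0]
                    frames = (
                        cycle * seq.recorded_per_cycle
                        + rec_block * block_len
                        + np.arange(n_obs)
                    )
                    rows.append(
                        pd.DataFrame(
                            {
                                "cell_id": cell_id,
                                "trajectory_id": tid,
                                "frame": frames,
                                "x_um": obs[:, 0],
                                "y_um": obs[:, 1],
                                "epoch": EPOCH_LABELS[rec_block],
                                "cycle": cycle,
                                "interacting": bool(interacting[m]),
                                "route": route,
                                "state_D": D,
                                "state_label": label,
                            }
                        )
                    )
                    tid += 1
        truth_rows.append(
            {
                "cell_id": cell_id,
                "n_molecules": n_mol,
                "n_interacting": int(interacting.sum()),
                "n_react_papa": n_react["papa"],
                "n_react_dr": n_react["dr"],
            }
        )
    locs = (
        pd.concat(rows, ignore_index=True) if rows
        else pd.DataFrame(
            columns=[
                "cell_id", "trajectory_id", "frame", "x_um", "y_um",
                "epoch", "cycle", "interacting", "route", "state_D",
                "state_label",
            ]
        )
    )
    return PAPAExperiment(
        locs=locs,
        cell_truth=pd.DataFrame(truth_rows),
        sequence=seq,
        sim=sim,
        papa=papa,
    )
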