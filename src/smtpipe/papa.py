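"""Proximity-assisted photoactivation (PAPA) analysis.

A PAPA-SMT acquisition interleaves unrecorded illumination blocks (red
bleaching, a green PAPA pulse, a violet direct-reactivation pulse) with
recorded 30-frame imaging blocks. Per cycle the recorded frames map to four
epochs: pre_PAPA, post_PAPA, pre_DR, post_DR. Trajectories reactivated by
the green pulse (PAPA class) report sender-proximal receivers; trajectories
reactivated by the violet pulse (DR class) are the proximity-independent
internal control. Reactivation per cell is quantified as the difference in
localization counts between the post- and pre-pulse imaging blocks, and the
PAPA-versus-DR relation across cells is summarized by a linear fit whose
residual trend flags saturation (sublinearity) for interacting pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "EPOCH_LABELS",
    "IlluminationSequence",
    "EpochLabel",
    "PAPACellSummary",
    "PAPARegression",
    "assign_epoch",
    "split_by_reactivation",
    "reactivation_summary",
    "papa_dr_regression",
    "spectra_by_class",
]

#: Epoch of each recorded 30-frame imaging block within one cycle.
EPOCH_LABELS = ("pre_PAPA", "post_PAPA", "pre_DR", "post_DR")


@dataclass
class IlluminationSequence:
    """One PAPA illumination cycle and its recorded-frame bookkeeping.

    Default cycle (frames): bleach 200, image 30, green 5, image 30,
    bleach 200, image 30, violet 1, image 30 — only the four imaging
    blocks are recorded, so each of 5 cycles contributes 120 recorded
    frames (600 total) at 7.48 ms/frame.
    """

    block_lengths: tuple[int, ...] = (200, 30, 5, 30, 200, 30, 1, 30)
    n_cycles: int = 5
    dt: float = 0.00748

    def __post_init__(self) -> None:
        if len(self.block_lengths) != 8:
            raise ValueError("a cycle has 8 blocks")
        rec = self.block_lengths[1::2]
        if len(set(rec)) != 1:
            raise ValueError("recorded imaging blocks must share one length")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def frames_per_block(self) -> int:
        return int(self.block_lengths[1])

    @property
    def recorded_per_cycle(self) -> int:
        return 4 * self.frames_per_block

    @property
    def n_recorded(self) -> int:
        return self.n_cycles * self.recorded_per_cycle


@dataclass(frozen=True)
class EpochLabel:
    label: str
    cycle: int


@dataclass
class PAPACellSummary:
    """Per-cell reactivation counts and their pre/post differences."""

    cell_id: int
    delta_papa: int
    delta_dr: int
    epoch_counts: dict = field(default_factory=dict)


@dataclass
class PAPARegression:
    """OLS fit of delta_papa on delta_dr across cells."""

    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray
    delta_dr: np.ndarray
    sublinearity_rho: float  # rank corr. of residuals with delta_dr
    sublinearity_p: float  # permutation p-value of that trend


def assign_epoch(recorded_frame_index: int, seq: IlluminationSequence) -> EpochLabel:
    """Map a recorded-frame index to its illumination epoch and cycle.

    Block within cycle: (index mod recorded_per_cycle) div frames_per_block,
    mapped 0 -> pre_PAPA, 1 -> post_PAPA, 2 -> pre_DR, 3 -> post_DR.
    """
    idx = int(recorded_frame_index)
    if not 0 <= idx < seq.n_recorded:
        raise ValueError(
            f"recorded frame index {idx} outside [0, {seq.n_recorded})"
        )
    per = seq.recorded_per_cycle
    block = (idx % per) // seq.frames_per_block
    return EpochLabel(label=EPOCH_LABELS[block], cycle=idx // per)


def _epoch_block(frames: np.ndarray, seq: IlluminationSequence) -> np.ndarray:
    """Global recorded-block index (cycle * 4 + block) for each frame."""
    frames = np.asarray(frames, dtype=int)
    if frames.size and (frames.min() < 0 or frames.max() >= seq.n_recorded):
        raise ValueError("recorded frame index outside the sequence")
    return frames // seq.frames_per_block


def split_by_reactivation(
    trajs: pd.DataFrame, seq: IlluminationSequence
) -> dict[str, pd.DataFrame]:
    """Sort trajectories into PAPA, DR and baseline classes.

    Input: localization table with columns trajectory (or trajectory_id)
    and frame (recorded index). A trajectory must lie within a single
    imaging block — links spanning a block boundary would bridge
    unrecorded real time and raise.
    """
    tcol = "trajectory" if "trajectory" in trajs.columns else "trajectory_id"
    keys = (["cell_id", tcol] if "cell_id" in trajs.columns else [tcol])
    out = {"PAPA": [], "DR": [], "baseline": []}
    if len(trajs):
        blocks = _epoch_block(trajs["frame"].to_numpy(), seq)
        work = trajs.assign(_block=blocks)
        spans = work.groupby(keys)["_block"].nunique()
        bad = spans[spans > 1]
        if len(bad):
            raise ValueError(
                f"trajectory {bad.index[0]!r} spans an imaging-block "
                "boundary (links crossed unrecorded time)"
            )
        class_map = {0: "baseline", 1: "PAPA", 2: "baseline", 3: "DR"}
        cls = (work.groupby(keys)["_block"].transform("first") % 4) \
            .map(class_map)
        for name in out:
            out[name] = work[cls == name].drop(columns="_block")
    return {
        k: (v.reset_index(drop=True) if len(v) else trajs.iloc[0:0].copy())
        for k, v in out.items()
    }


def reactivation_summary(
    locs: pd.DataFrame, seq: IlluminationSequence, cell_id: int | None = None
) -> PAPACellSummary:
    """Per-cell reactivation deltas from localization counts.

    delta_papa sums count(post_PAPA) - count(pre_PAPA) over cycles;
    delta_dr sums count(post_DR) - count(pre_DR). These are
    localization-level statistics, independent of trajectory linking.
    """
    if cell_id is None:
        cell_id = int(locs["cell_id"].iloc[0]) if "cell_id" in locs.columns \
            and len(locs) else -1
    counts = {label: 0 for label in EPOCH_LABELS}
    if len(locs):
        blocks = _epoch_block(locs["frame"].to_numpy(), seq) % 4
        for b, c in zip(*np.unique(blocks, return_counts=True)):
            counts[EPOCH_LABELS[int(b)]] = int(c)
    return PAPACellSummary(
        cell_id=cell_id,
        delta_papa=counts["post_PAPA"] - counts["pre_PAPA"],
        delta_dr=counts["post_DR"] - counts["pre_DR"],
        epoch_counts=counts,
    )


def papa_dr_regression(
    summaries: list[PAPACellSummary],
    n_permutations: int = 2000,
    seed: int = 0,
) -> PAPARegression:
    """Linear fit of PAPA on DR reactivation across cells, plus a
    saturation diagnostic.

    The diagnostic is the Spearman correlation between the fit residuals
    and delta_dr over the upper half of the delta_dr range (saturation
    shows as residuals turning negative at high DR; with a fitted
    intercept the full-range residual pattern of a concave relation is
    U-shaped and would cancel). A permutation p-value accompanies it:
    interacting (sender-limited) conditions give a negative high-DR
    trend; in non-interacting controls it is indistinguishable from zero.
    """
    if len(summaries) < 3:
        raise ValueError("regression needs >= 3 cells")
    x = np.array([s.delta_dr for s in summaries], dtype=float)
    y = np.array([s.delta_papa for s in summaries], dtype=float)
    if np.var(x) == 0:
        raise ValueError("zero variance in delta_dr")
    res = sstats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    hi = x >= np.median(x)
    rho, _ = sstats.spearmanr(resid[hi], x[hi])
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = sstats.spearmanr(rng.permutation(resid)[hi], x[hi])[0]
    p_perm = float((np.sum(np.abs(null) >= abs(rho)) + 1)
                   / (n_permutations + 1))
    return PAPARegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residuals=resid,
        delta_dr=x,
        sublinearity_rho=float(rho) if np.isfinite(rho) else 0.0,
        sublinearity_p=p_perm,
    )


def spectra_by_class(
    locs: pd.DataFrame,
    seq: IlluminationSequence,
    grid=None,
    bootstrap: bool = False,
    B: int = 100,
    seed: int = 0,
    threshold: float = 0.15,
) -> dict:
    """Diffusion spectra and f_bound for PAPA- versus DR-class trajectories.

    Splits by reactivation epoch, then runs occupation inference
    independently on each class (pooled over cells). With ``bootstrap``,
    cell-level bootstrap spreads are attached.
    """
    from .records import CellRecord, trajectories_from_table
    from .spectrum import DiffusionGrid, f_bound, infer_spectrum
    from .stats import bootstrap_fbound

    grid = grid if grid is not None else DiffusionGrid()
    classes = split_by_reactivation(locs, seq)
    out = {}
    for name in ("PAPA", "DR"):
        table = classes[name]
        if len(table) and "cell_id" in table.columns:
            trajs = [
                t for _, sub in table.groupby("cell_id", sort=True)
                for t in trajectories_from_table(sub)
            ]
        else:
            trajs = trajectories_from_table(table) if len(table) else []
        pos = [t.positions for t in trajs if len(t) >= 2]
        if not pos:
            raise ValueError(f"class {name!r} has no trajectory with a jump")
        spec = infer_spectrum(pos, grid)
        est = f_bound(spec, threshold=threshold)
        entry = {"spectrum": spec, "f_bound": est}
        if bootstrap:
            cells = []
            for cid, sub in table.groupby("cell_id", sort=True):
                cells.append(
                    CellRecord(
                        cell_id=int(cid),
                        trajectories=trajectories_from_table(sub),
                    )
                )
            if len(cells) >= 2:
                mean, sd = bootstrap_fbound(
                    cells, B=B, seed=seed, grid=grid, threshold=threshold,
                )
                entry["bootstrap_mean"] = mean
                entry["bootstrap_sd"] = sd
        out[name] = entry
    out["delta_fbound"] = (
        out["PAPA"]["f_bound"].value - out["DR"]["f_bound"].value
    )
    return out
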