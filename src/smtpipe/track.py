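"""Frame-to-frame trajectory linking and density quality control.

Two linking modes:

* ``euclidean`` — minimum-total-distance bipartite matching (Hungarian)
  between existing track heads and the next frame's detections, restricted
  to pairs within the search radius;
* ``conservative`` — a head links to a detection only when each is the
  other's unique neighbor within the search radius; every ambiguous
  detection starts a new trajectory (used for PAPA movies).

The search radius is denominated in microns. With ``max_blinks = 0`` (no
gap closing) output trajectories have strictly consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .config import TrackConfig

__all__ = [
    "link_euclidean",
    "link_conservative",
    "link",
    "apply_qc",
    "QCReport",
]

_BIG = 1e12


def _coords_um(locs: pd.DataFrame, cfg: TrackConfig) -> np.ndarray:
    if {"x_um", "y_um"}.issubset(locs.columns) \
            and locs[["x_um", "y_um"]].notna().all().all():
        return locs[["x_um", "y_um"]].to_numpy(dtype=float)
    return locs[["x", "y"]].to_numpy(dtype=float) * cfg.pixel_size


def _link_frames(
    locs: pd.DataFrame, cfg: TrackConfig, conservative: bool
) -> pd.DataFrame:
    if len(locs) == 0:
        out = locs.copy()
        out["trajectory"] = pd.Series(dtype=int)
        return out
    # keep the caller's row index so output rows stay identifiable
    locs = locs.sort_values("frame", kind="stable")
    xy = _coords_um(locs, cfg)
    frames = locs["frame"].to_numpy(dtype=int)
    traj = np.full(len(locs), -1, dtype=int)
    next_id = 0
    # active heads: row index of last localization + frame it was seen
    head_rows: list[int] = []
    head_frames: list[int] = []
    for f in np.unique(frames):
        det_idx = np.flatnonzero(frames == f)
        # retire heads that have been dark longer than max_blinks
        alive = [i for i, hf in enumerate(head_frames)
                 if f - hf <= cfg.max_blinks + 1]
        head_rows = [head_rows[i] for i in alive]
        head_frames = [head_frames[i] for i in alive]
        matched_det = np.zeros(det_idx.size, dtype=bool)
        matched_head = np.zeros(len(head_rows), dtype=bool)
        if head_rows and det_idx.size:
            D = cdist(xy[head_rows], xy[det_idx])
            within = D <= cfg.search_radius
            if conservative:
                # mutual uniqueness: exactly one candidate on both sides
                head_deg = within.sum(axis=1)
                det_deg = within.sum(axis=0)
                for hi in np.flatnonzero(head_deg == 1):
                    dj = int(np.flatnonzero(within[hi])[0])
                    if det_deg[dj] == 1:
                        matched_head[hi] = True
                        matched_det[dj] = True
                        traj[det_idx[dj]] = traj[head_rows[hi]]
            else:
                cost = np.where(within, D, _BIG)
                ri, cj = linear_sum_assignment(cost)
                for hi, dj in zip(ri, cj):
                    if within[hi, dj]:
                        matched_head[hi] = True
                        matched_det[dj] = True
                        traj[det_idx[dj]] = traj[head_rows[hi]]
        # update heads: matched continue, unmatched detections start tracks
        new_rows, new_frames = [], []
        for hi, row in enumerate(head_rows):
            if not matched_head[hi]:
                new_rows.append(row)
                new_frames.append(head_frames[hi])
        for dj, row in enumerate(det_idx):
            if not matched_det[dj]:
                traj[row] = next_id
                next_id += 1
            new_rows.append(int(row))
            new_frames.append(int(f))
        # matched heads must advance to the new localization row
        head_rows, head_frames = [], []
        seen = set()
        for row, hf in zip(new_rows, new_frames):
            tid = traj[row]
            if tid in seen:
                continue
            seen.add(tid)
            head_rows.append(row)
            head_frames.append(hf)
    out = locs.copy()
    out["trajectory"] = traj
    if cfg.min_spots > 1:
        sizes = out.groupby("trajectory")["trajectory"].transform("size")
        out = out[sizes >= cfg.min_spots].reset_index(drop=True)
    return out


def link_euclidean(locs: pd.DataFrame, cfg: TrackConfig) -> pd.DataFrame:
    """Hungarian minimum-total-distance linking within the search radius.

    Adds a ``trajectory`` column; every input row ends up in exactly one
    trajectory (possibly a singleton).
    """
    return _link_frames(locs, cfg, conservative=False)


def link_conservative(locs: pd.DataFrame, cfg: TrackConfig) -> pd.DataFrame:
    """Mutual-unique-neighbor linking; ambiguous detections start new
    trajectories. Links are a subset of the euclidean links."""
    return _link_frames(locs, cfg, conservative=True)


def link(locs: pd.DataFrame, cfg: TrackConfig) -> pd.DataFrame:
    """Dispatch on ``cfg.method``."""
    if cfg.method == "conservative":
        return link_conservative(locs, cfg)
    return link_euclidean(locs, cfg)


@dataclass
class QCReport:
    """Density/start-frame quality-control summary for one movie."""

    n_frames: int
    n_locs: int
    n_trajectories: int
    max_locs_per_frame: int
    flagged: bool
    offending_frames: list[int] = field(default_factory=list)
    start_frame: int = 0
    max_density: int = 5


def apply_qc(
    locs: pd.DataFrame,
    start_frame: int = 0,
    max_density: int = 5,
) -> tuple[pd.DataFrame, QCReport]:
    """Drop warm-up frames and flag over-dense movies.

    Records with ``frame < start_frame`` are removed. Movies with any
    retained frame holding more than ``max_density`` localizations are
    flagged (not silently dropped) — sparse data is a precondition of
    reliable linking.
    """
    kept = locs[locs["frame"] >= start_frame].reset_index(drop=True)
    if len(kept):
        per_frame = kept.groupby("frame").size()
        max_obs = int(per_frame.max())
        offending = per_frame[per_frame > max_density].index.astype(int).tolist()
    else:
        max_obs = 0
        offending = []
    n_traj = int(kept["trajectory"].nunique()) if "trajectory" in kept.columns \
        else 0
    report = QCReport(
        n_frames=int(kept["frame"].nunique()) if len(kept) else 0,
        n_locs=len(kept),
        n_trajectories=n_traj,
        max_locs_per_frame=max_obs,
        flagged=bool(offending),
        offending_frames=offending,
        start_frame=start_frame,
        max_density=max_density,
    )
    return kept, report
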