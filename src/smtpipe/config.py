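"""Configuration objects for the SMT pipeline.

Defaults follow the acquisition and processing settings used throughout the
package: 7.48 ms frame interval, 0.16 um pixels, a 0.7 um focal slab, EM-CCD
gain of 109 counts/photon over a 470-count offset, and the standard quot-style
detection/localization/tracking parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "SimState",
    "SimulationConfig",
    "OpticsConfig",
    "PAPAConfig",
    "DetectConfig",
    "LocalizeConfig",
    "TrackConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class SimState:
    """One diffusive state of the simulated mixture.

    Parameters
    ----------
    D : float
        Diffusion coefficient in um^2/s. ``D <= ~0.05`` is indistinguishable
        from chromatin motion and plays the role of the "bound" state.
    occupancy : float
        Fraction of molecules in this state. Occupancies across a
        configuration's states must sum to 1.
    label : str
        Free-text tag carried through to ground-truth tables.
    """

    D: float
    occupancy: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"diffusion coefficient must be >= 0, got {self.D}")
        if not 0 <= self.occupancy <= 1:
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")


def _check_occupancies(states: Sequence[SimState]) -> None:
    total = sum(s.occupancy for s in states)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"state occupancies must sum to 1 (got {total!r})")


@dataclass
class SimulationConfig:
    """Ground-truth trajectory simulation settings.

    The defaults emulate a fast-SMT experiment on a nuclear transcription
    factor: a slow chromatin-bound state plus a fast freely diffusing state,
    35 nm localization error, 7.48 ms frames, and a 0.7 um detection slab.
    ``n_cells=20`` x ``traj_per_cell=500`` matches the cohort size required
    for a stable bound-fraction estimate (>=10,000 pooled trajectories from
    >=20 cells).
    """

    states: list[SimState] = field(
        default_factory=lambda: [
            SimState(D=0.02, occupancy=0.5, label="bound"),
            SimState(D=3.0, occupancy=0.5, label="free"),
        ]
    )
    sigma_loc: float = 0.035  # localization error s.d. per axis (um)
    dt: float = 0.00748  # frame interval (s)
    n_cells: int = 20
    traj_per_cell: int = 500
    fov: float = 10.24  # field edge length (um); 64 px at 0.16 um/px
    focal_depth: float = 0.7  # axial detection slab thickness (um)
    bleach_prob: float = 0.2  # per-frame photobleaching probability
    n_frames: int = 5000  # movie length; appearance times spread uniformly
    # (500 trajectories over 5000 frames keeps the rendered density near
    # 0.35 localizations/frame — the "most frames had 1 or less" sparsity
    # regime the detection and linking settings assume)
    allow_switching: bool = False  # state switching within a trajectory
    switch_rate: float = 0.0  # per-frame switching probability when enabled
    seed: int = 0

    def __post_init__(self) -> None:
        _check_occupancies(self.states)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.focal_depth <= 0:
            raise ValueError("focal_depth must be > 0")
        if not 0 <= self.bleach_prob <= 1:
            raise ValueError("bleach_prob must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class OpticsConfig:
    """Camera and PSF model for movie rendering."""

    pixel_size: float = 0.16  # um per pixel
    psf_sigma: float = 1.2  # PSF s.d. in pixels
    camera_gain: float = 109.0  # counts per photon
    camera_bg: float = 470.0  # count offset
    read_noise: float = 2.0  # counts s.d.
    frame_shape: tuple[int, int] = (64, 64)  # (H, W) pixels
    photons_median: float = 500.0  # lognormal photon budget per localization
    photons_sigma_log: float = 0.3
    clip_out_of_fov: bool = False  # clip coordinates instead of rejecting

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.camera_gain <= 0:
            raise ValueError("camera_gain must be > 0")


#: One PAPA illumination cycle: bleach 200, image 30, green 5, image 30,
#: bleach 200, image 30, violet 1, image 30 (frames; only imaging recorded).
DEFAULT_BLOCK_LENGTHS = (200, 30, 5, 30, 200, 30, 1, 30)


@dataclass
class PAPAConfig:
    """Proximity-assisted-photoactivation experiment structure.

    Receiver molecules start each cycle in the dark state. A green pulse
    reactivates dark receivers bound to a sender with ``p_papa_interacting``
    and unbound receivers with ``p_papa_background``; the violet pulse
    reactivates any dark receiver with ``p_dr`` regardless of proximity.
    """

    block_lengths: tuple[int, ...] = DEFAULT_BLOCK_LENGTHS
    n_cycles: int = 5
    frac_interacting: float = 0.5
    p_papa_interacting: float = 0.25
    p_papa_background: float = 0.02
    p_dr: float = 0.15
    # per-cell receiver count multiplier range (expression variability);
    # (1, 1) keeps every cell at traj_per_cell molecules
    cell_size_range: tuple[float, float] = (1.0, 1.0)
    # cap on sender-bound receivers per cell; a finite sender pool makes
    # PAPA reactivation saturate in high-expressing cells (sublinearity)
    sender_pool: int | None = None
    states_interacting: list[SimState] = field(
        default_factory=lambda: [
            SimState(D=0.02, occupancy=0.7, label="bound"),
            SimState(D=3.0, occupancy=0.3, label="free"),
        ]
    )
    states_free: list[SimState] = field(
        default_factory=lambda: [
            SimState(D=0.02, occupancy=0.2, label="bound"),
            SimState(D=3.0, occupancy=0.8, label="free"),
        ]
    )

    def __post_init__(self) -> None:
        for p in (self.frac_interacting, self.p_papa_interacting,
                  self.p_papa_background, self.p_dr):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_papa_interacting < self.p_papa_background:
            raise ValueError("p_papa_interacting must be >= p_papa_background")
        _check_occupancies(self.states_interacting)
        _check_occupancies(self.states_free)


@dataclass
class DetectConfig:
    """Log-likelihood-ratio spot detection settings (quot 'llr' dialect)."""

    k: float = 1.0  # detection kernel s.d. (px); 1.2 for PAPA movies
    w: int = 15  # square test window edge (px, odd)
    t: float = 18.0  # LLR acceptance threshold
    start_frame: int = 0  # first retained frame (500 or 1000 for raw movies)

    def __post_init__(self) -> None:
        if self.w < 3 or self.w % 2 == 0:
            raise ValueError("w must be odd and >= 3")
        if self.t <= 0:
            raise ValueError("t must be > 0")


@dataclass
class LocalizeConfig:
    """Damped least-squares integrated-Gaussian localization settings."""

    window: int = 9  # fit box edge (px, odd)
    psf_sigma: float = 1.2  # fixed PSF s.d. (px)
    ridge: float = 1e-4  # Levenberg-style regularization
    max_iter: int = 20  # 10 in the PAPA settings block
    damp: float = 0.3
    camera_gain: float = 109.0
    camera_bg: float = 470.0
    conv_tol: float = 1e-6  # step-norm convergence threshold (px)

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if not 0 < self.damp <= 1:
            raise ValueError("damp must be in (0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class TrackConfig:
    """Frame-to-frame trajectory linking settings.

    ``search_radius`` is denominated in microns (1 um = 6.25 px at 0.16
    um/px): a 1-px radius would truncate free-state jumps, whose r.m.s.
    2D displacement at 10 um^2/s and 7.48 ms already exceeds 0.5 um.
    ``min_IO`` and ``scale`` are carried for config-dialect fidelity but
    have no effect here.
    """

    method: str = "euclidean"  # or "conservative"
    search_radius: float = 1.0  # um
    max_blinks: int = 0  # allowed gap frames
    min_spots: int = 1  # minimum localizations per kept trajectory
    pixel_size: float = 0.16  # um
    dt: float = 0.00748  # s
    min_IO: float = 0.0  # inert, dialect fidelity
    scale: float = 7.0  # inert, dialect fidelity

    def __post_init__(self) -> None:
        if self.method not in ("euclidean", "conservative"):
            raise ValueError(f"unknown linking method {self.method!r}")
        if self.search_radius <= 0:
            raise ValueError("search_radius must be > 0")
        if self.max_blinks < 0:
            raise ValueError("max_blinks must be >= 0")


_CONFIG_TYPES = {
    "simulation": SimulationConfig,
    "optics": OpticsConfig,
    "papa": PAPAConfig,
    "detect": DetectConfig,
    "localize": LocalizeConfig,
    "track": TrackConfig,
}


def _build(cls, payload):
    if cls is SimulationConfig:
        payload = dict(payload)
        if "states" in payload:
            payload["states"] = [SimState(**s) for s in payload["states"]]
        return cls(**payload)
    if cls is PAPAConfig:
        payload = dict(payload)
        for key in ("states_interacting", "states_free"):
            if key in payload:
                payload[key] = [SimState(**s) for s in payload[key]]
        if "block_lengths" in payload:
            payload["block_lengths"] = tuple(payload["block_lengths"])
        return cls(**payload)
    if cls is OpticsConfig and "frame_shape" in payload:
        payload = dict(payload)
        payload["frame_shape"] = tuple(payload["frame_shape"])
    return cls(**payload)


def load_config(path: str | Path) -> dict:
    """Read a YAML/JSON document with one section per pipeline stage.

    Recognized top-level keys: ``simulation``, ``optics``, ``papa``,
    ``detect``, ``localize``, ``track``. Returns a dict of config objects.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    out = {}
    for key, payload in raw.items():
        if key not in _CONFIG_TYPES:
            raise ValueError(f"unknown config section {key!r}")
        out[key] = _build(_CONFIG_TYPES[key], payload or {})
    return out


def save_config(configs: dict, path: str | Path) -> None:
    """Write config objects back to a YAML document (inverse of load_config)."""
    doc = {}
    for key, cfg in configs.items():
        if key not in _CONFIG_TYPES:
            raise ValueError(f"unknown config section {key!r}")
        doc[key] = asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
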