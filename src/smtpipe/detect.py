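"""Spot detection and sub-pixel localization.

Detection is a generalized log-likelihood-ratio (LLR) test per pixel: a
Gaussian spot of known s.d. ``k`` plus flat background against flat
background alone, over the surrounding ``w x w`` window, with the noise
variance estimated per window. With the mean-centered kernel ``g`` and
window pixel count ``n`` the statistic is

    LLR = -(n / 2) * log(1 - (g . y)^2 / (||g||^2 * RSS0))

where RSS0 is the window's residual sum of squares around its mean; all
terms are computable by convolution. Local maxima above the threshold
``t`` survive non-maximum suppression within radius w/2.

Localization fits the model ``bg + N * (pixel-integrated 2D Gaussian)``
to the photon-domain window around each candidate by damped Gauss-Newton
with ridge-regularized normal equations, the standard least-squares
integrated-Gaussian estimator.

Coordinate convention: pixel indices are 0-based and a localization at the
exact center of pixel (i, j) has coordinates (i, j); microns = px * pixel
size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d, maximum_filter, uniform_filter

from .config import DetectConfig, LocalizeConfig
from .records import Movie

__all__ = [
    "llr_detect",
    "localize_integrated_gaussian",
    "detect_and_localize_movie",
    "LOC_COLUMNS",
]

logger = logging.getLogger(__name__)

LOC_COLUMNS = ["frame", "y", "x", "y_um", "x_um", "photons", "bg", "llr",
               "converged"]


def _detection_kernel(k: float, w: int) -> np.ndarray:
    """Mean-centered Gaussian matched filter on the w x w window."""
    c = (w - 1) / 2.0
    ax = np.arange(w) - c
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * k * k))
    return g - g.mean()


def llr_detect(
    frame_image: np.ndarray, cfg: DetectConfig, frame_index: int = 0
) -> pd.DataFrame:
    """Candidate spot pixels with LLR scores for one frame.

    Returns a table with integer pixel coordinates (y, x) and the llr
    statistic, sorted by decreasing llr.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be 2D")
    if min(img.shape) < cfg.w:
        raise ValueError(f"frame dimensions must be >= w = {cfg.w}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"non-finite pixels in frame {frame_index}")
    w = cfg.w
    n = w * w
    ghat = _detection_kernel(cfg.k, w)
    gg = float(np.sum(ghat * ghat))
    # g is separable; the mean-centered correlation is
    # corr(img, g) - mean(g) * (windowed sum)
    c = (w - 1) / 2.0
    g1 = np.exp(-((np.arange(w) - c) ** 2) / (2.0 * cfg.k**2))
    S1 = uniform_filter(img, size=w, mode="reflect") * n
    A = correlate1d(
        correlate1d(img, g1, axis=0, mode="reflect"),
        g1, axis=1, mode="reflect",
    ) - np.outer(g1, g1).mean() * S1
    S2 = uniform_filter(img * img, size=w, mode="reflect") * n
    rss0 = S2 - S1 * S1 / n
    # windows with (numerically) zero variance carry no evidence of a spot
    span = float(img.max() - img.min())
    floor = n * (1e-9 * span) ** 2 + 1e-30
    u = np.where(
        rss0 > floor,
        np.clip(A * A / (gg * np.clip(rss0, floor, None)), 0.0, 1.0 - 1e-12),
        0.0,
    )
    llr_map = -(n / 2.0) * np.log1p(-u)
    # non-maximum suppression within radius w/2
    peaks = (llr_map >= cfg.t) & (
        llr_map == maximum_filter(llr_map, size=w, mode="reflect")
    )
    ys, xs = np.nonzero(peaks)
    order = np.argsort(llr_map[ys, xs])[::-1]
    return pd.DataFrame(
        {"y": ys[order], "x": xs[order], "llr": llr_map[ys, xs][order]}
    )


def _integrated_axis(coords: np.ndarray, mu: np.ndarray, sigma: float):
    """Per-axis pixel-integrated Gaussian E and its derivative dE/dmu.

    coords: (win,) pixel indices; mu: (C, 1) centers. Returns (C, win).
    """
    from scipy.special import erf

    s2 = sigma * np.sqrt(2.0)
    hi = (coords[None, :] + 0.5 - mu) / s2
    lo = (coords[None, :] - 0.5 - mu) / s2
    E = 0.5 * (erf(hi) - erf(lo))
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    dE = norm * (
        np.exp(-((coords[None, :] - 0.5 - mu) ** 2) / (2 * sigma * sigma))
        - np.exp(-((coords[None, :] + 0.5 - mu) ** 2) / (2 * sigma * sigma))
    )
    return E, dE


def _fit_windows(data: np.ndarray, cfg: LocalizeConfig):
    """Batched damped Gauss-Newton on photon-domain windows (C, win, win).

    Returns window-local (y, x), photons, bg, converged, failed arrays.
    """
    C, win, _ = data.shape
    hw = win // 2
    n = win * win
    flat = data.reshape(C, n)
    # parameters in window-local coordinates (center pixel at hw)
    py = np.full(C, float(hw))
    px = np.full(C, float(hw))
    bg = np.min(flat, axis=1)
    N = np.clip(flat.sum(axis=1) - n * bg, 1e-3, None)
    converged = np.zeros(C, dtype=bool)
    failed = np.zeros(C, dtype=bool)
    coords = np.arange(win, dtype=float)
    eye = np.eye(4) * cfg.ridge

    active = np.ones(C, dtype=bool)
    for _ in range(cfg.max_iter):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        Ey, dEy = _integrated_axis(coords, py[ai, None], cfg.psf_sigma)
        Ex, dEx = _integrated_axis(coords, px[ai, None], cfg.psf_sigma)
        shape = Ey[:, :, None] * Ex[:, None, :]  # (c, win, win)
        model = bg[ai, None, None] + N[ai, None, None] * shape
        r = (data[ai] - model).reshape(len(ai), n)
        J = np.empty((len(ai), n, 4))
        J[:, :, 0] = (N[ai, None, None] * dEy[:, :, None]
                      * Ex[:, None, :]).reshape(len(ai), n)
        J[:, :, 1] = (N[ai, None, None] * Ey[:, :, None]
                      * dEx[:, None, :]).reshape(len(ai), n)
        J[:, :, 2] = shape.reshape(len(ai), n)
        J[:, :, 3] = 1.0
        JtJ = np.einsum("cni,cnj->cij", J, J) + eye
        Jtr = np.einsum("cni,cn->ci", J, r)
        try:
            step = np.linalg.solve(JtJ, Jtr[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.zeros((len(ai), 4))
            for j in range(len(ai)):
                try:
                    step[j] = np.linalg.solve(JtJ[j], Jtr[j])
                except np.linalg.LinAlgError:
                    failed[ai[j]] = True
        step *= cfg.damp
        py[ai] += step[:, 0]
        px[ai] += step[:, 1]
        N[ai] += step[:, 2]
        bg[ai] += step[:, 3]
        done = np.linalg.norm(step[:, :2], axis=1) < cfg.conv_tol
        converged[ai[done]] = True
        active[ai[done | failed[ai]]] = False
    return py, px, N, bg, converged, failed


def _extract_windows(img: np.ndarray, ys: np.ndarray, xs: np.ndarray,
                     win: int) -> np.ndarray:
    hw = win // 2
    data = np.empty((ys.size, win, win))
    for i in range(ys.size):
        data[i] = img[ys[i] - hw: ys[i] + hw + 1, xs[i] - hw: xs[i] + hw + 1]
    return data


def _assemble_locs(frames, ys, xs, py, px, N, bg, llrs, converged, failed,
                   H, W, hw, pixel_size):
    y_fit = ys - hw + py
    x_fit = xs - hw + px
    ok = (
        (N >= 0)
        & (y_fit >= -0.5) & (y_fit <= H - 0.5)
        & (x_fit >= -0.5) & (x_fit <= W - 0.5)
    )
    out = pd.DataFrame(
        {
            "frame": np.broadcast_to(frames, ys.shape)[ok],
            "y": y_fit[ok],
            "x": x_fit[ok],
            "photons": N[ok],
            "bg": bg[ok],
            "llr": llrs[ok],
            "converged": (converged & ~failed)[ok],
        }
    )
    ps = pixel_size if pixel_size is not None else np.nan
    out["y_um"] = out["y"] * ps
    out["x_um"] = out["x"] * ps
    return out[LOC_COLUMNS]


def localize_integrated_gaussian(
    frame_image: np.ndarray,
    candidates: pd.DataFrame,
    cfg: LocalizeConfig,
    frame_index: int = 0,
    pixel_size: float | None = None,
) -> pd.DataFrame:
    """Damped Gauss-Newton least-squares fits around candidate pixels.

    The image is converted to the photon domain, ``(counts - camera_bg) /
    camera_gain``; within each fit window the parameters (y, x, N, bg) of
    ``bg + N * E_y E_x^T`` are iterated with steps ``damp * (J^T J +
    ridge I)^{-1} J^T r`` until the positional step norm falls below the
    convergence threshold or ``max_iter`` is reached. Candidates whose fit
    window leaves the frame are dropped; fits that push the position out
    of the frame or to negative photons are discarded. Singular normal
    equations flag the record non-converged rather than raising.
    """
    img = (np.asarray(frame_image, dtype=float) - cfg.camera_bg) \
        / cfg.camera_gain
    H, W = img.shape
    hw = cfg.window // 2
    ys = candidates["y"].to_numpy(dtype=int)
    xs = candidates["x"].to_numpy(dtype=int)
    keep = (ys >= hw) & (ys < H - hw) & (xs >= hw) & (xs < W - hw)
    ys, xs = ys[keep], xs[keep]
    llrs = candidates["llr"].to_numpy()[keep] if "llr" in candidates \
        else np.full(ys.size, np.nan)
    if ys.size == 0:
        return pd.DataFrame(columns=LOC_COLUMNS)
    data = _extract_windows(img, ys, xs, cfg.window)
    py, px, N, bg, converged, failed = _fit_windows(data, cfg)
    return _assemble_locs(
        np.full(ys.size, frame_index), ys, xs, py, px, N, bg, llrs,
        converged, failed, H, W, hw, pixel_size,
    )


def detect_and_localize_movie(
    movie: Movie, dcfg: DetectConfig, lcfg: LocalizeConfig
) -> pd.DataFrame:
    """Detect and localize every retained frame of a movie.

    Frames before ``dcfg.start_frame`` (the high-density warm-up at the
    start of raw acquisitions) are skipped. Output follows the quot CSV
    dialect: frame, y, x, y_um, x_um, photons, bg, llr, converged.
    """
    H, W = movie.shape
    hw = lcfg.window // 2
    all_f, all_y, all_x, all_llr, windows = [], [], [], [], []
    for f in range(dcfg.start_frame, movie.n_frames):
        cands = llr_detect(movie.frames[f], dcfg, frame_index=f)
        if not len(cands):
            continue
        ys = cands["y"].to_numpy(dtype=int)
        xs = cands["x"].to_numpy(dtype=int)
        keep = (ys >= hw) & (ys < H - hw) & (xs >= hw) & (xs < W - hw)
        if not keep.any():
            continue
        ys, xs = ys[keep], xs[keep]
        img = (movie.frames[f].astype(float) - lcfg.camera_bg) \
            / lcfg.camera_gain
        windows.append(_extract_windows(img, ys, xs, lcfg.window))
        all_f.append(np.full(ys.size, f))
        all_y.append(ys)
        all_x.append(xs)
        all_llr.append(cands["llr"].to_numpy()[keep])
    if not windows:
        return pd.DataFrame(columns=LOC_COLUMNS)
    data = np.concatenate(windows)
    frames = np.concatenate(all_f)
    ys = np.concatenate(all_y)
    xs = np.concatenate(all_x)
    llrs = np.concatenate(all_llr)
    py, px, N, bg, converged, failed = _fit_windows(data, lcfg)
    out = _assemble_locs(frames, ys, xs, py, px, N, bg, llrs,
                         converged, failed, H, W, hw, movie.pixel_size)
    logger.debug(
        "detect_and_localize_movie: %d frames, %d localizations",
        movie.n_frames - dcfg.start_frame, len(out),
    )
    return out
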