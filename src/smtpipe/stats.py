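"""Cohort-level statistics for bound-fraction estimates.

The paper-style error model: cells are the unit of biological replication,
so uncertainty on a pooled f_bound is obtained by resampling cells with
replacement (B = 100 draws) and recomputing the pooled estimate on each
resample. Conditions are compared with a two-tailed normal test on the
difference of bootstrap means (variance = sum of bootstrap variances) and
the Sidak correction for the family of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .records import CellRecord
from .spectrum import (
    DiffusionGrid,
    FBoundEstimate,
    estimate_bleach_survival,
    evaluate_likelihood_grid,
    expected_jumps_weights,
    f_bound,
    infer_occupations,
)

__all__ = [
    "ConditionSummary",
    "ComparisonResult",
    "SubsampleCurve",
    "cell_likelihood_rows",
    "pooled_fbound",
    "bootstrap_fbound",
    "bootstrap_fbound_values",
    "summarize_condition",
    "sidak",
    "compare_conditions",
    "subsample_analysis",
    "mean_intensity",
    "correlate_intensity_fbound",
]


@dataclass
class ConditionSummary:
    """Per-condition pooled bound fraction with bootstrap spread."""

    label: str
    pooled_fbound: float
    bootstrap_mean: float
    bootstrap_sd: float
    B: int = 100
    n_cells: int = 0
    n_trajectories: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_sd < 0:
            raise ValueError("bootstrap_sd must be >= 0")


@dataclass
class ComparisonResult:
    """Pairwise condition comparison with Sidak-adjusted p-value."""

    label_a: str
    label_b: str
    delta: float
    z: float
    p_raw: float
    p_adjusted: float
    m: int
    stars: str = ""
    degenerate: bool = False


@dataclass
class SubsampleCurve:
    """f_bound stability versus cohort size.

    ``table`` has one row per requested (n_cells, n_trajectories) size with
    the subsample mean, s.d. and bias relative to the full-data estimate.
    """

    table: pd.DataFrame
    full_value: float
    R: int


def cell_likelihood_rows(
    cells: list[CellRecord], grid: DiffusionGrid
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-cell (likelihood rows, jump weights); cached by callers that
    resample cells so the grid evaluation runs once."""
    out = []
    for cell in cells:
        trajs = cell.positions_list()
        if trajs:
            out.append(evaluate_likelihood_grid(trajs, grid))
        else:
            out.append((np.zeros((0, grid.n_states)), np.zeros(0, dtype=int)))
    return out


def _correction_weights(
    L: np.ndarray, w: np.ndarray, grid: DiffusionGrid
) -> np.ndarray:
    """Per-D expected-jumps divisors for a cohort (computed once, shared
    across bootstrap/subsample draws of the same cohort)."""
    beta = estimate_bleach_survival(L, w, grid)
    return expected_jumps_weights(grid, beta)


def _fbound_from_rows(
    L: np.ndarray,
    w: np.ndarray,
    grid: DiffusionGrid,
    threshold: float,
    corr: np.ndarray,
    theta0: np.ndarray | None,
    tol: float,
    max_iter: int,
) -> tuple[float, np.ndarray]:
    post = infer_occupations(
        L, w, grid, tol=tol, max_iter=max_iter, theta0=theta0
    )
    theta = post.occupations
    occ = post.occupations_2d / corr[:, None]
    marg = occ.sum(axis=1) / occ.sum()
    value = float(marg[grid.D_values < threshold].sum())
    return min(value, 1.0), theta


def pooled_fbound(
    cells: list[CellRecord],
    grid: DiffusionGrid | None = None,
    threshold: float = 0.15,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> FBoundEstimate:
    """Pooled (all cells jointly) defocalization-corrected bound fraction."""
    grid = grid if grid is not None else DiffusionGrid()
    rows = cell_likelihood_rows(cells, grid)
    L = np.vstack([r[0] for r in rows])
    w = np.concatenate([r[1] for r in rows])
    if L.shape[0] == 0:
        raise ValueError("no trajectories with at least one jump")
    corr = _correction_weights(L, w, grid)
    value, _ = _fbound_from_rows(
        L, w, grid, threshold, corr, None, tol, max_iter
    )
    est = FBoundEstimate(
        value=value, threshold=threshold,
        n_cells=len(cells), n_trajectories=int(L.shape[0]),
    )
    return est


def bootstrap_fbound(
    cells: list[CellRecord],
    B: int = 100,
    seed: int = 0,
    grid: DiffusionGrid | None = None,
    threshold: float = 0.15,
    tol: float = 1e-7,
    max_iter: int = 200,
    return_draws: bool = False,
):
    """Cell-level bootstrap of the pooled bound fraction.

    Each of the B draws resamples n cells with replacement and recomputes
    the pooled, jump-weighted f_bound on the resampled trajectory set.
    Per-cell likelihood rows are evaluated once and reused; each draw's EM
    is warm-started from the full-data optimum. A resample with zero jumps
    is redrawn (and counted in the returned log).

    Returns (mean, sd) over draws, or (mean, sd, draws) if requested.
    """
    if len(cells) < 2:
        raise ValueError("bootstrap needs >= 2 cells")
    grid = grid if grid is not None else DiffusionGrid()
    rng = np.random.default_rng(seed)
    rows = cell_likelihood_rows(cells, grid)
    L_full = np.vstack([r[0] for r in rows])
    w_full = np.concatenate([r[1] for r in rows])
    corr = _correction_weights(L_full, w_full, grid)
    _, theta_full = _fbound_from_rows(
        L_full, w_full, grid, threshold, corr, None, 1e-8, 2000
    )
    n = len(cells)
    draws = np.empty(B)
    n_redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            w = np.concatenate([rows[i][1] for i in idx])
            if w.size > 0:
                break
            n_redraws += 1
        L = np.vstack([rows[i][0] for i in idx])
        draws[b], _ = _fbound_from_rows(
            L, w, grid, threshold, corr, theta_full, tol, max_iter
        )
    if n_redraws:
        import logging

        logging.getLogger(__name__).info(
            "bootstrap_fbound: %d empty resample(s) redrawn", n_redraws
        )
    mean, sd = float(draws.mean()), float(draws.std(ddof=1))
    if return_draws:
        return mean, sd, draws
    return mean, sd


def bootstrap_fbound_values(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    B: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Fast approximation: resample per-cell f_bound values (weighted mean
    pooling) instead of re-running inference on resampled trajectories."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("bootstrap needs >= 2 cells")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    vw = values * w
    draws = vw[idx].sum(axis=1) / w[idx].sum(axis=1)
    return float(draws.mean()), float(draws.std(ddof=1))


def summarize_condition(
    label: str,
    cells: list[CellRecord],
    B: int = 100,
    seed: int = 0,
    grid: DiffusionGrid | None = None,
    threshold: float = 0.15,
) -> ConditionSummary:
    """Pooled f_bound plus cell-level bootstrap, packaged for comparison."""
    grid = grid if grid is not None else DiffusionGrid()
    est = pooled_fbound(cells, grid, threshold=threshold)
    mean, sd = bootstrap_fbound(
        cells, B=B, seed=seed, grid=grid, threshold=threshold
    )
    return ConditionSummary(
        label=label,
        pooled_fbound=est.value,
        bootstrap_mean=mean,
        bootstrap_sd=sd,
        B=B,
        n_cells=len(cells),
        n_trajectories=est.n_trajectories,
    )


def sidak(p_raw: float, m: int) -> float:
    """Sidak family-wise adjustment: 1 - (1 - p)^m for m comparisons."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p_raw must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if p_raw == 1.0:
        return 1.0
    return float(-np.expm1(m * np.log1p(-p_raw)))


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_conditions(
    a: ConditionSummary, b: ConditionSummary, m: int = 1
) -> ComparisonResult:
    """Two-tailed normal comparison of bootstrap means, Sidak-adjusted.

    z = (mean_a - mean_b) / sqrt(sd_a^2 + sd_b^2); p_raw = 2 Phi(-|z|);
    p_adjusted = 1 - (1 - p_raw)^m. The family size m (comparisons
    reported together) must be given explicitly.
    """
    delta = a.bootstrap_mean - b.bootstrap_mean
    var = a.bootstrap_sd**2 + b.bootstrap_sd**2
    degenerate = var == 0.0
    if degenerate:
        z = 0.0 if delta == 0 else np.inf * np.sign(delta)
        p_raw = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var)
        p_raw = float(2.0 * sstats.norm.sf(abs(z)))
    p_adj = sidak(p_raw, m)
    return ComparisonResult(
        label_a=a.label,
        label_b=b.label,
        delta=float(delta),
        z=float(z),
        p_raw=p_raw,
        p_adjusted=p_adj,
        m=m,
        stars=_stars(p_adj),
        degenerate=degenerate,
    )


def subsample_analysis(
    cells: list[CellRecord],
    sizes: list[tuple[int, int]],
    R: int = 10,
    seed: int = 0,
    grid: DiffusionGrid | None = None,
    threshold: float = 0.15,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> SubsampleCurve:
    """f_bound stability versus (n_cells, n_trajectories) subsample size.

    For each size, R subsamples are drawn without replacement (cells first,
    then trajectories pooled across the drawn cells); the pooled f_bound of
    each subsample is recomputed, and bias is reported against the
    full-data estimate.
    """
    grid = grid if grid is not None else DiffusionGrid()
    rng = np.random.default_rng(seed)
    rows = cell_likelihood_rows(cells, grid)
    n_per_cell = [r[1].size for r in rows]
    feasible = (len(cells), int(np.sum(n_per_cell)))
    for nc, nt in sizes:
        if nc > feasible[0] or nt > feasible[1]:
            raise ValueError(
                f"requested size (cells={nc}, trajectories={nt}) exceeds the "
                f"data (cells={feasible[0]}, trajectories={feasible[1]})"
            )
    L_full = np.vstack([r[0] for r in rows])
    w_full = np.concatenate([r[1] for r in rows])
    corr = _correction_weights(L_full, w_full, grid)
    full_value, theta_full = _fbound_from_rows(
        L_full, w_full, grid, threshold, corr, None, 1e-8, 2000
    )
    out = []
    for nc, nt in sizes:
        vals = np.empty(R)
        for r in range(R):
            cell_idx = rng.choice(len(cells), size=nc, replace=False)
            Ls = np.vstack([rows[i][0] for i in cell_idx])
            ws = np.concatenate([rows[i][1] for i in cell_idx])
            avail = ws.size
            take = min(nt, avail)
            sel = rng.choice(avail, size=take, replace=False)
            vals[r], _ = _fbound_from_rows(
                Ls[sel], ws[sel], grid, threshold, corr,
                theta_full, tol, max_iter,
            )
        out.append(
            {
                "n_cells": nc,
                "n_trajectories": nt,
                "mean_fbound": float(vals.mean()),
                "sd_fbound": float(vals.std(ddof=1)) if R > 1 else 0.0,
                "bias": float(vals.mean() - full_value),
            }
        )
    return SubsampleCurve(table=pd.DataFrame(out), full_value=full_value, R=R)


def mean_intensity(movie, mask: np.ndarray | None = None) -> float:
    """Average over frames of the per-frame mean pixel value (expression
    proxy from the pre-bleach movie), optionally within a nucleus mask."""
    frames = np.asarray(movie.frames if hasattr(movie, "frames") else movie,
                        dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("movie must have >= 1 frame")
    if mask is not None:
        per_frame = frames[:, mask].mean(axis=1)
    else:
        per_frame = frames.mean(axis=(1, 2))
    return float(per_frame.mean())


@dataclass
class IntensityCorrelation:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    degenerate: bool = False


def correlate_intensity_fbound(
    intensities: np.ndarray, fbound_values: np.ndarray
) -> IntensityCorrelation:
    """Pearson and Spearman correlation across cells of (mean intensity,
    per-cell f_bound) — the expression-versus-binding relation."""
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(fbound_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired cells")
    if np.std(x) == 0 or np.std(y) == 0:
        return IntensityCorrelation(
            np.nan, np.nan, np.nan, np.nan, x.size, degenerate=True
        )
    pr, pp = sstats.pearsonr(x, y)
    sr, sp = sstats.spearmanr(x, y)
    return IntensityCorrelation(
        float(pr), float(pp), float(sr), float(sp), x.size
    )
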