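"""Diffusion-spectrum inference from short single-molecule trajectories.

The model is regular Brownian motion with Gaussian localization error
(RBME). For a trajectory observed at consecutive frames with interval
``dt``, the per-axis vector of jumps ``d`` is zero-mean multivariate normal
with tridiagonal covariance

    Sigma[l, l]   = 2 D dt + 2 sigma^2
    Sigma[l, l+1] = -sigma^2

where ``D`` is the diffusion coefficient and ``sigma`` the localization
error s.d.; the anti-correlation of consecutive jumps is the signature of
localization error. Trajectory likelihoods are evaluated on a fixed grid of
(D, sigma) states, and the occupation of each state in the population is
estimated by expectation-maximization on the jump-weighted mixture
likelihood. Occupations are corrected post hoc for defocalization (fast
molecules leave the finite focal slab and are under-observed), and the
chromatin-bound fraction ``f_bound`` is the corrected occupation mass at
D below 0.15 um^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.fft import dst
from scipy.linalg import cholesky_banded, cho_solve_banded
from scipy.special import erf, logsumexp

__all__ = [
    "DiffusionGrid",
    "SpectrumPosterior",
    "FBoundEstimate",
    "rbme_log_likelihood",
    "evaluate_likelihood_grid",
    "infer_occupations",
    "defocalization_weights",
    "expected_jumps_weights",
    "estimate_bleach_survival",
    "apply_defocalization",
    "marginal_posterior",
    "f_bound",
    "infer_spectrum",
]

_LOG2PI = float(np.log(2.0 * np.pi))

#: The bound/free boundary on the diffusion-coefficient axis (um^2/s).
FBOUND_THRESHOLD = 0.15


def _default_D_grid(n: int = 100, lo: float = 0.01, hi: float = 100.0) -> np.ndarray:
    """Log-spaced D grid with the point nearest the f_bound threshold
    snapped to exactly 0.15 um^2/s, so the strict '<' cut is unambiguous."""
    D = np.geomspace(lo, hi, n)
    D[np.argmin(np.abs(D - FBOUND_THRESHOLD))] = FBOUND_THRESHOLD
    return D


@dataclass
class DiffusionGrid:
    """Fixed state grid for spectrum inference.

    Defaults: 100 log-spaced diffusion coefficients spanning [0.01, 100]
    um^2/s (one grid point at exactly 0.15) by 6 localization-error values
    in [0.02, 0.06] um; 7.48 ms frames; 0.7 um focal slab.
    """

    D_values: np.ndarray = field(default_factory=_default_D_grid)
    sigma_values: np.ndarray = field(
        default_factory=lambda: np.linspace(0.02, 0.06, 6)
    )
    dt: float = 0.00748
    focal_depth: float = 0.7

    def __post_init__(self) -> None:
        self.D_values = np.asarray(self.D_values, dtype=float)
        self.sigma_values = np.asarray(self.sigma_values, dtype=float)
        if np.any(np.diff(self.D_values) <= 0):
            raise ValueError("D_values must be strictly increasing")
        if np.any(np.diff(self.sigma_values) <= 0):
            raise ValueError("sigma_values must be strictly increasing")
        if self.dt <= 0 or self.focal_depth <= 0:
            raise ValueError("dt and focal_depth must be > 0")

    @property
    def n_states(self) -> int:
        return self.D_values.size * self.sigma_values.size

    def state_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (D, sigma) per state, D-major ordering."""
        D, S = np.meshgrid(self.D_values, self.sigma_values, indexing="ij")
        return D.ravel(), S.ravel()


@dataclass
class SpectrumPosterior:
    """State occupations on a DiffusionGrid.

    ``occupations`` is a flat vector over the D-major (D, sigma) grid,
    summing to 1. ``marginal_D`` is the diffusion spectrum proper.
    """

    occupations: np.ndarray
    grid: DiffusionGrid
    scope: str = "pooled"  # or "cell"
    n_jumps: int = 0
    n_trajectories: int = 0
    converged: bool = True
    n_iter: int = 0
    loglik_trace: np.ndarray | None = None
    defocalization_corrected: bool = False

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupations, dtype=float)
        if occ.size != self.grid.n_states:
            raise ValueError("occupations do not match grid size")
        if np.any(occ < -1e-12):
            raise ValueError("occupations must be nonnegative")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError("occupations must sum to 1")
        self.occupations = occ

    @property
    def occupations_2d(self) -> np.ndarray:
        nD = self.grid.D_values.size
        nS = self.grid.sigma_values.size
        return self.occupations.reshape(nD, nS)

    @property
    def marginal_D(self) -> np.ndarray:
        return self.occupations_2d.sum(axis=1)


@dataclass
class FBoundEstimate:
    """Chromatin-bound fraction: occupation mass strictly below threshold."""

    value: float
    threshold: float = FBOUND_THRESHOLD
    n_cells: int = 0
    n_trajectories: int = 0
    bootstrap_sd: float | None = None
    bootstrap_mean: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"f_bound must lie in [0, 1], got {self.value}")


def _as_jumps(traj: np.ndarray) -> np.ndarray:
    """Positions (n, 2) in um -> jumps (n-1, 2). Raises on fewer than 2 points."""
    pos = np.asarray(traj, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("trajectory must be an (n, 2) array of positions in um")
    if pos.shape[0] < 2:
        raise ValueError("no jumps: trajectory has fewer than 2 points")
    return np.diff(pos, axis=0)


def _banded_cholesky(L: int, D: float, sigma: float, dt: float):
    """Upper-banded Cholesky of the L x L RBME jump covariance."""
    ab = np.zeros((2, L))
    ab[0, 1:] = -sigma * sigma
    ab[1, :] = 2.0 * D * dt + 2.0 * sigma * sigma
    cb = cholesky_banded(ab, lower=False)
    logdet = 2.0 * np.sum(np.log(cb[1]))
    return cb, logdet


def rbme_log_likelihood(traj: np.ndarray, D: float, sigma: float, dt: float) -> float:
    """Log-likelihood of one trajectory under (D, sigma).

    Parameters
    ----------
    traj : (n, 2) array
        Consecutive-frame positions in um (gaps must be excluded upstream).
    D, sigma, dt : float
        Diffusion coefficient (um^2/s), localization error s.d. (um),
        frame interval (s).

    Evaluated stably through the Cholesky factorization of the tridiagonal
    jump covariance; the two lateral axes are independent and summed.
    """
    jumps = _as_jumps(traj)
    L = jumps.shape[0]
    cb, logdet = _banded_cholesky(L, D, sigma, dt)
    sol = cho_solve_banded((cb, False), jumps)
    quad = float(np.sum(jumps * sol))
    return -0.5 * (quad + 2.0 * logdet + 2.0 * L * _LOG2PI)


def evaluate_likelihood_grid(
    trajs: Sequence[np.ndarray],
    grid: DiffusionGrid,
    normalize: bool = True,
    log: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trajectory likelihoods over all grid states.

    Parameters
    ----------
    trajs : sequence of (n_i, 2) position arrays (um)
        Every trajectory needs at least one jump.
    grid : DiffusionGrid
    normalize : bool
        If True each row is normalized to sum to 1 (the per-trajectory
        state posterior under a uniform prior). Row scaling is irrelevant
        to the downstream mixture EM.

    Returns
    -------
    L : (n_traj, n_states) array, D-major state ordering
    n_jumps : (n_traj,) int array (downstream evidence weights)
    """
    jumps_list = [_as_jumps(t) for t in trajs]
    n_traj = len(jumps_list)
    lengths = np.array([j.shape[0] for j in jumps_list])
    nD, nS = grid.D_values.size, grid.sigma_values.size
    logL = np.empty((n_traj, nD * nS))
    D_flat, S_flat = grid.state_arrays()
    a = 2.0 * D_flat * grid.dt + 2.0 * S_flat**2  # diagonal per state
    b = -(S_flat**2)  # off-diagonal per state

    # The tridiagonal Toeplitz covariance diagonalizes in the DST-I basis:
    # eigenvalues a + 2 b cos(k pi / (L + 1)); quadratic forms for all
    # states of one length group reduce to a single matrix product.
    for L_jumps in np.unique(lengths):
        idx = np.flatnonzero(lengths == L_jumps)
        X = np.hstack([jumps_list[i] for i in idx])  # (L, 2 * n_group)
        Xt = dst(X, type=1, norm="ortho", axis=0)
        cosk = np.cos(np.arange(1, L_jumps + 1) * np.pi / (L_jumps + 1))
        lam = a[None, :] + 2.0 * b[None, :] * cosk[:, None]  # (L, n_states)
        quad = (Xt * Xt).T @ (1.0 / lam)  # (2 * n_group, n_states)
        logdet = np.sum(np.log(lam), axis=0)  # (n_states,)
        per_axis = -0.5 * (quad + logdet[None, :] + L_jumps * _LOG2PI)
        logL[idx, :] = (
            per_axis.reshape(len(idx), 2, -1).sum(axis=1)
        )

    if not np.all(np.isfinite(logL.max(axis=1))):
        bad = int(np.flatnonzero(~np.isfinite(logL.max(axis=1)))[0])
        raise FloatingPointError(
            f"likelihood underflow for trajectory {bad}: all states at -inf"
        )
    if normalize:
        logL -= logsumexp(logL, axis=1, keepdims=True)
    return (logL if log else np.exp(logL)), lengths


def infer_occupations(
    likelihoods: np.ndarray,
    weights: np.ndarray,
    grid: DiffusionGrid,
    tol: float = 1e-8,
    max_iter: int = 2000,
    theta0: np.ndarray | None = None,
    scope: str = "pooled",
    keep_trace: bool = False,
) -> SpectrumPosterior:
    """Maximum-likelihood state occupations by EM.

    Maximizes ``sum_i w_i log sum_j theta_j L_ij`` over the simplex with a
    flat (Dirichlet alpha = 1) prior. The E-step computes responsibilities
    ``r_ij propto theta_j L_ij``; the M-step sets ``theta_j`` to the
    weighted mean responsibility. Iterates until ``max |d theta| < tol`` or
    ``max_iter``; non-convergence returns the best iterate flagged.
    """
    L = np.asarray(likelihoods, dtype=float)
    w = np.asarray(weights, dtype=float)
    if L.ndim != 2 or L.shape[0] != w.size:
        raise ValueError("likelihood matrix and weights are inconsistent")
    if np.any(w < 1):
        raise ValueError("weights must be >= 1 (jump counts)")
    n, K = L.shape
    if K != grid.n_states:
        raise ValueError("likelihood matrix does not match grid size")
    W = w.sum()
    theta = (
        np.full(K, 1.0 / K) if theta0 is None
        else np.asarray(theta0, dtype=float) / np.sum(theta0)
    )

    trace = [] if keep_trace else None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = L @ theta  # (n,)
        if np.any(denom <= 0):
            raise FloatingPointError("zero mixture likelihood encountered")
        if trace is not None:
            trace.append(float(np.dot(w, np.log(denom))))
        theta_new = theta * (L.T @ (w / denom)) / W
        delta = float(np.max(np.abs(theta_new - theta)))
        theta = theta_new
        if delta < tol:
            converged = True
            break
    theta = np.clip(theta, 0.0, None)
    theta /= theta.sum()

    return SpectrumPosterior(
        occupations=theta,
        grid=grid,
        scope=scope,
        n_jumps=int(w.sum()),
        n_trajectories=n,
        converged=converged,
        n_iter=it,
        loglik_trace=None if trace is None else np.asarray(trace),
    )


def defocalization_weights(
    grid: DiffusionGrid,
    n_lags: int = 4,
    n_bins: int = 200,
) -> np.ndarray:
    """Slab-survival fraction per grid D.

    For each diffusion coefficient, the fraction of molecules starting
    uniformly inside the focal slab ``|z| <= focal_depth / 2`` that remain
    inside for ``n_lags`` consecutive axial Brownian steps of s.d.
    ``sqrt(2 D dt)``, computed by propagating the discretized 1D
    concentration profile with the exact Gaussian bin-transition kernel.
    Dividing occupations by these fractions compensates the
    under-observation of fast states.
    """
    if n_lags < 0:
        raise ValueError("n_lags must be >= 0")
    survival = np.ones_like(grid.D_values)
    if n_lags == 0:
        return survival
    for i, D in enumerate(grid.D_values):
        survival[i] = _slab_survival_curve(
            float(D), grid, n_lags, n_bins
        )[-1]
    return survival


def _slab_survival_curve(
    D: float, grid: DiffusionGrid, max_lags: int, n_bins: int = 200
) -> np.ndarray:
    """S_l for l = 1..max_lags: slab survival through l consecutive steps."""
    h = grid.focal_depth / 2.0
    s = np.sqrt(2.0 * D * grid.dt)
    if s == 0.0:
        return np.ones(max_lags)
    edges = np.linspace(-h, h, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    z = (edges[:, None] - centers[None, :]) / (s * np.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    T = cdf[1:, :] - cdf[:-1, :]
    p = np.full(n_bins, 1.0 / n_bins)
    out = np.empty(max_lags)
    for l in range(max_lags):
        p = T @ p
        out[l] = p.sum()
    return out


def expected_jumps_weights(
    grid: DiffusionGrid,
    bleach_survival: float,
    max_lags: int = 60,
    n_bins: int = 200,
) -> np.ndarray:
    """Expected observed jumps per activated molecule, per grid D.

    E[J | D] = sum_l beta^l S_l(D), where beta is the per-frame fluorophore
    survival probability and S_l the probability of staying inside the
    focal slab for l consecutive axial steps (uniform start). With
    jump-count weighting the raw occupations estimate each state's share
    of *jumps*, which over-represents slow states whose tracks last
    longer; dividing by E[J | D] converts jump shares into molecule
    fractions exactly.

    Returned weights drop the D-independent leading factor beta (it
    cancels on renormalization), so they remain well defined as
    beta -> 0, where they reduce to the one-step survival S_1(D).
    """
    if not 0 <= bleach_survival < 1:
        raise ValueError("bleach_survival must lie in [0, 1)")
    beta_pow = bleach_survival ** np.arange(0, max_lags)
    out = np.empty_like(grid.D_values)
    for i, D in enumerate(grid.D_values):
        S = _slab_survival_curve(float(D), grid, max_lags, n_bins)
        out[i] = float(np.dot(beta_pow, S))
    return out


def estimate_bleach_survival(
    likelihoods: np.ndarray,
    n_jumps: np.ndarray,
    grid: DiffusionGrid,
    D_slow: float = FBOUND_THRESHOLD,
) -> float:
    """Per-frame fluorophore survival from slow-trajectory track lengths.

    Slow (bound-like) molecules do not leave the focal slab, so their
    frame counts are geometric with continuation probability beta. Among
    analyzed trajectories (>= 1 jump) the jump count J then satisfies
    E[J | J >= 1] = 1 / (1 - beta), i.e. beta = 1 - 1 / mean(J).
    Trajectories are classed slow when their maximum-likelihood grid state
    has D < D_slow; if none qualify, all trajectories are used
    (conservative fallback).
    """
    D_flat, _ = grid.state_arrays()
    best_D = D_flat[np.argmax(likelihoods, axis=1)]
    slow = best_D < D_slow
    J = np.asarray(n_jumps, dtype=float)
    mean_J = float(J[slow].mean()) if slow.any() else float(J.mean())
    return float(np.clip(1.0 - 1.0 / mean_J, 0.0, 0.999))


def apply_defocalization(
    spectrum: SpectrumPosterior,
    n_lags: int = 4,
    method: str = "survival",
    bleach_survival: float | None = None,
    max_lags: int = 60,
) -> SpectrumPosterior:
    """Correct occupations for defocalization and renormalize.

    ``method='survival'`` divides by the slab-survival fraction over
    ``n_lags`` steps; ``method='expected_jumps'`` divides by the expected
    observed jumps per molecule (requires ``bleach_survival``), which is
    the consistent correction for jump-count-weighted occupations.
    """
    if method == "survival":
        surv = defocalization_weights(spectrum.grid, n_lags=n_lags)
    elif method == "expected_jumps":
        if bleach_survival is None:
            raise ValueError("expected_jumps correction needs bleach_survival")
        surv = expected_jumps_weights(
            spectrum.grid, bleach_survival, max_lags=max_lags
        )
    else:
        raise ValueError(f"unknown correction method {method!r}")
    occ = spectrum.occupations_2d / surv[:, None]
    occ = occ.ravel() / occ.sum()
    return SpectrumPosterior(
        occupations=occ,
        grid=spectrum.grid,
        scope=spectrum.scope,
        n_jumps=spectrum.n_jumps,
        n_trajectories=spectrum.n_trajectories,
        converged=spectrum.converged,
        n_iter=spectrum.n_iter,
        loglik_trace=spectrum.loglik_trace,
        defocalization_corrected=True,
    )


def marginal_posterior(spectrum: SpectrumPosterior):
    """Diffusion spectrum as a table: D, occupation (PDF mass), CDF."""
    import pandas as pd

    pdf = spectrum.marginal_D
    return pd.DataFrame(
        {
            "D": spectrum.grid.D_values,
            "occupation": pdf,
            "cdf": np.cumsum(pdf),
        }
    )


def f_bound(
    spectrum: SpectrumPosterior, threshold: float = FBOUND_THRESHOLD
) -> FBoundEstimate:
    """Occupation mass at D strictly below ``threshold`` (default 0.15 um^2/s)."""
    D = spectrum.grid.D_values
    if not (D[0] <= threshold <= D[-1]):
        raise ValueError(
            f"threshold {threshold} outside grid span [{D[0]}, {D[-1]}]"
        )
    value = float(spectrum.marginal_D[D < threshold].sum())
    return FBoundEstimate(
        value=min(value, 1.0),
        threshold=threshold,
        n_trajectories=spectrum.n_trajectories,
    )


def infer_spectrum(
    trajs: Sequence[np.ndarray],
    grid: DiffusionGrid | None = None,
    correct_defocalization: bool = True,
    correction: str = "expected_jumps",
    n_lags: int = 4,
    scope: str = "pooled",
    tol: float = 1e-8,
    max_iter: int = 2000,
    theta0: np.ndarray | None = None,
) -> SpectrumPosterior:
    """Likelihood grid + EM + defocalization correction, in one call.

    The default correction divides occupations by the expected observed
    jumps per molecule (slab survival combined with the bleaching survival
    estimated from slow-track lengths); ``correction='survival'`` uses the
    plain ``n_lags``-step slab-survival fraction instead.
    """
    grid = grid if grid is not None else DiffusionGrid()
    L, n_jumps = evaluate_likelihood_grid(trajs, grid)
    post = infer_occupations(
        L, n_jumps, grid, tol=tol, max_iter=max_iter, theta0=theta0, scope=scope
    )
    if correct_defocalization:
        if correction == "expected_jumps":
            beta = estimate_bleach_survival(L, n_jumps, grid)
            post = apply_defocalization(
                post, method="expected_jumps", bleach_survival=beta
            )
        else:
            post = apply_defocalization(post, n_lags=n_lags, method=correction)
    return post
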