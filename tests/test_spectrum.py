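"""Diffusion-spectrum inference: likelihood, EM, defocalization, f_bound."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from smtpipe.spectrum import (
    DiffusionGrid,
    SpectrumPosterior,
    apply_defocalization,
    defocalization_weights,
    estimate_bleach_survival,
    evaluate_likelihood_grid,
    expected_jumps_weights,
    f_bound,
    infer_occupations,
    infer_spectrum,
    marginal_posterior,
    rbme_log_likelihood,
)

DT = 0.00748


def dense_rbme_logpdf(jumps, D, sigma, dt):
    """Independent oracle: explicit tridiagonal covariance + generic dense
    multivariate-normal evaluation, per axis."""
    L = jumps.shape[0]
    cov = np.diag(np.full(L, 2 * D * dt + 2 * sigma**2))
    cov += np.diag(np.full(L - 1, -(sigma**2)), 1)
    cov += np.diag(np.full(L - 1, -(sigma**2)), -1)
    mvn = multivariate_normal(mean=np.zeros(L), cov=cov)
    return mvn.logpdf(jumps[:, 0]) + mvn.logpdf(jumps[:, 1])


class TestRbmeLogLikelihood:
    def test_single_zero_jump_closed_form(self):
        # per-axis variance 2 D dt + 2 sigma^2 = 0.017410 um^2 at the
        # standard frame interval; density of a zero jump is 1/(2 pi v)
        traj = np.zeros((2, 2))
        v = 2 * 1.0 * DT + 2 * 0.035**2
        ll = rbme_log_likelihood(traj, D=1.0, sigma=0.035, dt=DT)
        assert np.isclose(v, 0.017410, atol=5e-7)
        assert np.isclose(ll, -np.log(2 * np.pi * v), rtol=1e-12)
        assert np.isclose(ll, 2.2128, atol=1e-3)

    def test_zero_sigma_factorizes_over_jumps(self):
        rng = np.random.default_rng(1)
        traj = np.cumsum(rng.normal(0, 0.1, size=(6, 2)), axis=0)
        jumps = np.diff(traj, axis=0)
        D = 0.8
        per_jump = -0.5 * (
            jumps**2 / (2 * D * DT) + np.log(2 * np.pi * 2 * D * DT)
        ).sum()
        assert np.isclose(
            rbme_log_likelihood(traj, D=D, sigma=0.0, dt=DT), per_jump,
            rtol=1e-12,
        )

    def test_matches_dense_solver(self):
        rng = np.random.default_rng(2)
        traj = np.cumsum(rng.normal(0, 0.05, size=(5, 2)), axis=0)
        jumps = np.diff(traj, axis=0)
        ll = rbme_log_likelihood(traj, D=0.5, sigma=0.03, dt=DT)
        assert abs(ll - dense_rbme_logpdf(jumps, 0.5, 0.03, DT)) < 1e-10

    def test_fewer_than_two_points_raises(self):
        with pytest.raises(ValueError, match="no jumps"):
            rbme_log_likelihood(np.zeros((1, 2)), 1.0, 0.03, DT)


class TestLikelihoodGrid:
    def test_rows_normalized_and_concentrate_on_truth(
        self, make_trajectories
    ):
        # grid resolution matched to 8-jump information content
        # (relative s.d. of a per-trajectory D estimate ~ sqrt(1/(2 L)))
        grid = DiffusionGrid(
            D_values=np.geomspace(0.01, 100, 16),
            sigma_values=np.array([0.025, 0.035, 0.045]),
        )
        rng = np.random.default_rng(3)
        iD = 10  # a grid D in the free range
        D = grid.D_values[iD]
        trajs = make_trajectories(rng, 200, 8, D, 0.035)
        L, n_jumps = evaluate_likelihood_grid(trajs, grid)
        assert np.allclose(L.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(n_jumps == 8)
        best_D = grid.state_arrays()[0][np.argmax(L, axis=1)]
        # argmax within one grid step of the truth for >= 90% of rows
        lo, hi = grid.D_values[iD - 1], grid.D_values[iD + 1]
        assert np.mean((best_D >= lo) & (best_D <= hi)) >= 0.9

    def test_single_jump_rows_are_broad(self, small_grid, make_trajectories):
        rng = np.random.default_rng(4)
        short = make_trajectories(rng, 50, 1, 1.0, 0.035)
        long = make_trajectories(rng, 50, 8, 1.0, 0.035)
        def mean_entropy(trajs):
            L, _ = evaluate_likelihood_grid(trajs, small_grid)
            P = np.clip(L, 1e-300, None)
            return float(np.mean(-(P * np.log(P)).sum(axis=1)))
        assert mean_entropy(short) > mean_entropy(long)

    def test_doubling_dt_halves_mode_D(self, make_trajectories):
        rng = np.random.default_rng(5)
        trajs = make_trajectories(rng, 300, 8, 2.0, 0.0)
        grids = [
            DiffusionGrid(sigma_values=np.array([0.001, 0.002]), dt=dt)
            for dt in (DT, 2 * DT)
        ]
        modes = []
        for g in grids:
            L, w = evaluate_likelihood_grid(trajs, g)
            post = infer_occupations(L, w, g, max_iter=300)
            modes.append(g.D_values[np.argmax(post.marginal_D)])
        assert np.isclose(modes[1], modes[0] / 2, rtol=0.15)


class TestInferOccupations:
    def test_identical_single_state_rows_give_point_mass(self, small_grid):
        K = small_grid.n_states
        L = np.zeros((40, K))
        L[:, 17] = 1.0
        post = infer_occupations(L, np.full(40, 4), small_grid)
        assert post.occupations[17] > 1 - 1e-6

    def test_em_loglik_monotone(self, small_grid, make_trajectories):
        rng = np.random.default_rng(6)
        trajs = make_trajectories(rng, 150, 5, 0.02, 0.035) \
            + make_trajectories(rng, 150, 5, 3.0, 0.035)
        L, w = evaluate_likelihood_grid(trajs, small_grid)
        post = infer_occupations(L, w, small_grid, max_iter=200,
                                 keep_trace=True)
        diffs = np.diff(post.loglik_trace)
        assert np.all(diffs >= -1e-9)

    def test_em_matches_one_parameter_scan(self, small_grid,
                                           make_trajectories):
        """On a two-column mixture the EM optimum must agree with a dense
        brute-force scan over the single mixture weight."""
        rng = np.random.default_rng(7)
        trajs = make_trajectories(rng, 400, 6, 0.02, 0.035) \
            + make_trajectories(rng, 400, 6, 3.0, 0.035)
        grid2 = DiffusionGrid(
            D_values=np.array([0.02, 3.0]),
            sigma_values=np.array([0.035]),
        )
        L2, w = evaluate_likelihood_grid(trajs, grid2)
        post = infer_occupations(L2, w, grid2, tol=1e-12, max_iter=20000)
        # brute-force scan of sum_i w_i log(lam L_i1 + (1-lam) L_i2)
        lam = np.linspace(1e-6, 1 - 1e-6, 200001)
        mix = np.outer(L2[:, 0], lam) + np.outer(L2[:, 1], 1 - lam)
        ll = (w[:, None] * np.log(mix)).sum(axis=0)
        lam_star = lam[np.argmax(ll)]
        assert abs(post.occupations[0] - lam_star) < 1e-4

    def test_invalid_weights_rejected(self, small_grid):
        L = np.full((3, small_grid.n_states), 1.0 / small_grid.n_states)
        with pytest.raises(ValueError):
            infer_occupations(L, np.zeros(3), small_grid)


class TestDefocalization:
    def test_immobile_survival_is_one(self):
        grid = DiffusionGrid(
            D_values=np.array([0.0, 1.0]), sigma_values=np.array([0.03, 0.04])
        )
        w = defocalization_weights(grid, n_lags=4)
        assert w[0] == pytest.approx(1.0)

    def test_monotone_in_D_and_lags(self, small_grid):
        w1 = defocalization_weights(small_grid, n_lags=1)
        w4 = defocalization_weights(small_grid, n_lags=4)
        assert np.all(np.diff(w1) <= 1e-12)
        assert np.all(w4 <= w1 + 1e-12)
        # strictly decreasing where escape is non-negligible
        fast = small_grid.D_values > 0.5
        assert np.all(np.diff(w1[fast]) < 0)

    def test_survival_matches_monte_carlo(self):
        grid = DiffusionGrid(
            D_values=np.array([1.0, 3.5]),
            sigma_values=np.array([0.03, 0.04]),
        )
        surv = defocalization_weights(grid, n_lags=1)[1]
        rng = np.random.default_rng(8)
        n = 1_000_000
        z0 = rng.uniform(-0.35, 0.35, n)
        z1 = z0 + rng.normal(0, np.sqrt(2 * 3.5 * DT), n)
        inside = np.abs(z1) <= 0.35
        p_hat = inside.mean()
        se = np.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(surv - p_hat) < 3 * se

    def test_expected_jumps_reduce_to_geometric_for_immobile(self):
        grid = DiffusionGrid(
            D_values=np.array([0.0, 0.5, 5.0]),
            sigma_values=np.array([0.03, 0.04]),
        )
        beta = 0.8
        w = expected_jumps_weights(grid, beta, max_lags=200)
        # immobile molecules never leave the slab: E[J] = beta / (1 - beta);
        # the returned weights drop the constant leading beta factor
        assert np.isclose(w[0], 1.0 / (1 - beta), rtol=1e-3)
        assert np.all(np.diff(w) <= 1e-12)

    def test_bleach_survival_estimated_from_slow_track_lengths(
        self, small_grid, make_trajectories
    ):
        rng = np.random.default_rng(9)
        beta = 0.75
        lengths = rng.geometric(1 - beta, size=400)
        trajs = []
        for L in lengths:
            trajs.extend(make_trajectories(rng, 1, int(L), 0.02, 0.035))
        Lm, w = evaluate_likelihood_grid(trajs, small_grid)
        est = estimate_bleach_survival(Lm, w, small_grid)
        assert abs(est - beta) < 0.05


class TestSpectrumAndFbound:
    def _point_mass(self, grid, iD, iS=0):
        occ = np.zeros(grid.n_states)
        occ[iD * grid.sigma_values.size + iS] = 1.0
        return SpectrumPosterior(occupations=occ, grid=grid)

    def test_point_mass_cdf_is_step(self, small_grid):
        spec = self._point_mass(small_grid, 10)
        tab = marginal_posterior(spec)
        assert np.isclose(tab["cdf"].iloc[-1], 1.0, atol=1e-9)
        step = np.searchsorted(tab["cdf"].to_numpy(), 0.5)
        assert step == 10

    def test_fbound_extremes(self, small_grid):
        lo = self._point_mass(small_grid, 0)
        assert f_bound(lo).value == pytest.approx(1.0)
        iD_5 = int(np.argmin(np.abs(small_grid.D_values - 5.0)))
        hi = self._point_mass(small_grid, iD_5)
        assert f_bound(hi).value == pytest.approx(0.0)

    def test_threshold_cut_is_strict(self, default_grid):
        # the default grid carries a point at exactly 0.15; mass there
        # does not count as bound
        iD = int(np.flatnonzero(default_grid.D_values == 0.15)[0])
        spec = self._point_mass(default_grid, iD)
        assert f_bound(spec, threshold=0.15).value == pytest.approx(0.0)

    def test_threshold_outside_grid_raises(self, small_grid):
        spec = self._point_mass(small_grid, 3)
        with pytest.raises(ValueError, match="outside grid"):
            f_bound(spec, threshold=1000.0)

    def test_mixture_recovery_before_correction(self, small_grid,
                                                make_trajectories):
        # 50/50 mixture at matched trajectory lengths: slow-mass below
        # 0.15 um^2/s recovers 0.50 within 0.03 without any correction
        rng = np.random.default_rng(10)
        trajs = make_trajectories(rng, 1000, 8, 0.01, 0.035) \
            + make_trajectories(rng, 1000, 8, 5.0, 0.035)
        L, w = evaluate_likelihood_grid(trajs, small_grid)
        post = infer_occupations(L, w, small_grid, max_iter=500)
        slow = post.marginal_D[small_grid.D_values < 0.15].sum()
        assert abs(slow - 0.5) < 0.03
        cdf = np.cumsum(post.marginal_D)
        plateau = cdf[np.argmin(np.abs(small_grid.D_values - 0.5))]
        assert abs(plateau - 0.5) < 0.03

    def test_pooling_consistency(self, make_trajectories):
        # pooled spectrum of N identical cells equals a single cell's
        rng = np.random.default_rng(11)
        grid = DiffusionGrid(
            D_values=np.geomspace(0.01, 100, 20),
            sigma_values=np.array([0.03, 0.04]),
        )
        one = make_trajectories(rng, 100, 5, 0.5, 0.035)
        single = infer_spectrum(one, grid, correct_defocalization=False,
                                max_iter=400)
        pooled = infer_spectrum(one * 3, grid, correct_defocalization=False,
                                max_iter=400)
        assert np.allclose(single.occupations, pooled.occupations, atol=5e-4)

    def test_occupation_validation(self, small_grid):
        with pytest.raises(ValueError, match="sum to 1"):
            SpectrumPosterior(
                occupations=np.full(small_grid.n_states, 0.5),
                grid=small_grid,
            )
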