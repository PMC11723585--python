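# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `smtpipe`. It is written for a user who wants to understand
what the package computes and what its validation on synthetic data does —
and does not — establish about real single-molecule-tracking (SMT) data.

## The measurement being emulated

Fast SMT images sparse, photoactivated dye-labeled nuclear proteins at
7.48 ms/frame under HILO illumination. Detections are linked into short
trajectories; the population of trajectories mixes molecules bound to
chromatin (apparent diffusion indistinguishable from chromatin motion,
D ≲ 0.05 µm²/s) with freely diffusing molecules (1–10 µm²/s). The analysis
goal is the *diffusion spectrum* — the posterior occupation of a grid of
diffusion coefficients — and its functional

    f_bound = occupation mass at D < 0.15 µm²/s,

the operational chromatin-bound fraction. PAPA-SMT adds a protein–protein
interaction readout: green light reactivates dark "receiver" fluorophores
only when a "sender"-labeled partner is nearby (PAPA), while violet light
reactivates receivers indiscriminately (direct reactivation, DR), giving an
internal control population.

## Trajectory likelihood (RBME)

For a trajectory observed at consecutive frames with interval `dt`, the
per-axis vector of jumps `d` under Brownian motion with Gaussian
localization error (s.d. σ per axis) is zero-mean multivariate normal with
tridiagonal covariance

    Σ_ll   = 2 D dt + 2 σ²,      Σ_l,l+1 = −σ².

The negative off-diagonal is the signature of localization error:
consecutive jumps share the error of their common point. The two lateral
axes are independent and their log-densities are summed.

Two evaluation routes are implemented and cross-checked in the tests:

* `rbme_log_likelihood` — banded Cholesky factorization of Σ (the
  reference implementation, numerically stable for any trajectory length);
* `evaluate_likelihood_grid` — a spectral route exploiting that Σ is
  tridiagonal *Toeplitz*: its eigenvectors form the DST-I basis and its
  eigenvalues are `a + 2b cos(kπ/(L+1))`, so the quadratic forms for all
  grid states of one trajectory-length group reduce to one matrix product
  after a single orthonormal sine transform of the jumps. Both routes agree
  with a dense multivariate-normal oracle to better than 1e-8 (the
  acceptance suite measures ~1e-12).

Likelihood rows are normalized per trajectory via log-sum-exp; underflow in
the normalized matrix is impossible by construction, and a row whose states
are all at −inf raises rather than propagating NaNs.

## State grid

Default grid: 100 log-spaced diffusion coefficients spanning
[0.01, 100] µm²/s crossed with 6 localization-error values in
[0.02, 0.06] µm. Neither axis is prescribed by the measurement itself; the
span brackets both populations seen in nuclear-receptor data and typical
optical precision. The grid point closest to 0.15 µm²/s is snapped to
exactly 0.15 and the f_bound cut is strict (`D < 0.15`), so the boundary
convention is visible and testable. `dt` defaults to 0.00748 s (the
acquisition frame interval; a processing-settings variant 0.00747 exists in
the wild — the difference is 0.01% and 0.00748 is adopted everywhere).

## Occupation inference

State occupations θ maximize the jump-weighted mixture log-likelihood
`Σ_i w_i log Σ_j θ_j L_ij` (flat Dirichlet prior, α = 1) by plain EM:
responsibilities `r_ij ∝ θ_j L_ij`, then `θ_j ← Σ_i w_i r_ij / Σ_i w_i`.
Weights `w_i` are jump counts — longer trajectories carry proportionally
more evidence. Iteration stops when `max |Δθ| < 1e-8` (default) or at
`max_iter = 2000`; non-convergence returns the final iterate flagged. The
EM objective is non-decreasing by construction and this is asserted in
tests. In practice the simplex tolerance is rarely reached — EM creeps
along flat directions exchanging mass between adjacent grid states — but
f_bound is stable to ~0.002 after ~50 iterations and to ~5e-4 after 800;
bootstrap and subsampling draws therefore warm-start from the full-data
optimum and cap at 200 iterations, a purely numerical economy measured
to be far below the bootstrap spread it feeds.

A brute-force one-parameter scan of the same objective on two-state
problems is the correctness anchor: EM agrees with it to <1e-4 occupancy.

## Defocalization correction

Fast molecules leave the axial detection slab (thickness Δz = 0.7 µm) and
are under-observed. `defocalization_weights` computes, per grid D, the
fraction of molecules starting uniformly in the slab that remain inside for
`n_lags` consecutive axial steps of s.d. `sqrt(2 D dt)`, by propagating the
discretized 1D concentration profile with the exact Gaussian bin-transition
kernel (200 bins; validated against a 10⁶-walker Monte-Carlo simulation).

The *applied* correction goes one step further. Because occupations are
jump-weighted, the raw θ estimates each state's share of **jumps**, which
over-represents slow states whose tracks simply last longer — bleaching
limits a bound track while axial escape truncates a free one much earlier.
The consistent divisor is the expected number of observed jumps per
activated molecule,

    E[J | D] ∝ Σ_l β^(l−1) S_l(D),

where S_l is the l-step slab survival above and β is the per-frame
fluorophore survival probability, estimated from the data: slow-classified
trajectories cannot escape the slab, so their jump counts are geometric
and `β = 1 − 1/mean(J_slow)` (the analyzed population conditions on
J ≥ 1). A fixed-lag survival divisor (`method="survival"`, the simpler
convention) is retained as an option; numerically it is unbiased only when
the typical track length happens to match the chosen lag, and misestimates
a true f_bound of 0.5 by up to ±0.08 as the bleach rate varies, which is
why the expected-jumps form is the default. Corrected occupations are
renormalized; both corrections act only on the D axis.

## Detection and localization

Detection is a generalized log-likelihood-ratio test per pixel: Gaussian
spot of known s.d. `k` plus flat background versus flat background alone,
over a w×w window, with the noise variance estimated per window:

    LLR = −(n/2) log(1 − (ĝ·y)² / (‖ĝ‖² RSS0)),

with ĝ the mean-centered kernel and RSS0 the window's residual sum of
squares about its mean. All terms are windowed sums, computed by separable
convolution; the map is invariant to affine intensity changes. Candidates
are local maxima above threshold `t` after non-maximum suppression within
radius w/2. Windows with numerically zero variance are assigned LLR 0 (a
constant window carries no evidence of a spot). Defaults follow the
standard settings for this data: k = 1.0 (1.2 for PAPA movies), w = 15,
t = 18.

Localization converts counts to photons using the camera gain (109
counts/photon) and offset (470 counts), then fits
`bg + N · (pixel-integrated Gaussian, fixed σ = 1.2 px)` over a 9×9 window
by damped Gauss-Newton: step `damp·(JᵀJ + ridge·I)⁻¹ Jᵀr` with damp = 0.3,
ridge = 1e-4, at most 20 iterations (10 for PAPA), convergence at step norm
< 1e-6 px. With the fixed damping the asymptotic contraction is ~0.7 per
iteration, so the convergence flag is often false on noiseless fixtures
even when the position is accurate to <1e-3 px; the flag is reported
honestly rather than redefined. Fits are batched across all candidate
windows of a movie. Coordinates are 0-based pixel-center: a localization at
the center of pixel (i, j) is exactly (i, j); microns = px × 0.16.

Pitfalls by construction: candidates whose fit window leaves the frame are
dropped; fits producing negative photons or positions outside the frame are
discarded; singular normal equations flag the record rather than raise.

## Tracking

Frame-to-frame linking with search radius 1 **µm** (= 6.25 px at
0.16 µm/px — a 1-px reading would truncate free-state jumps, whose r.m.s.
2D displacement at 10 µm²/s already exceeds 0.5 µm per frame) and no gap
closing (max_blinks = 0, so output frames are strictly consecutive).
`euclidean` mode solves the minimum-total-distance bipartite assignment
(Hungarian) restricted to pairs within the radius; `conservative` mode (the
PAPA convention) links only mutually unique neighbor pairs, so its links
are a subset of the euclidean ones. Every input localization lands in
exactly one trajectory; singletons are kept (they carry no jumps and hence
no likelihood). The legacy settings tokens `min_IO` and `scale` are carried
in the config for dialect fidelity but are inert. Density QC drops frames
before `start_frame` (the high-density warm-up of raw acquisitions) and
flags — never silently edits — movies with more than 5 localizations in a
frame.

## Synthetic data generator

The generator is the study-conditions stand-in for raw movies, and every
downstream stage is scored against its ground truth.

* **Kinematics.** Each molecule draws a diffusive state from the
  configured occupancies (fixed per molecule by default; a switching flag
  exists for robustness experiments), appears at a uniformly random frame
  and position, and performs independent lateral (x, y) and axial (z)
  Brownian steps of per-axis s.d. `sqrt(2 D dt)`. It is observed while
  |z| ≤ Δz/2 and unbleached; observation ends at the first bleaching event
  or axial exit, with no re-entry (matching max_blinks = 0). Observed
  positions add Gaussian localization error (default σ = 0.035 µm, typical
  for this camera/dye combination).
* **Scale.** Defaults: 20 cells × 500 trajectories — the ≥10,000 pooled
  trajectories from ≥20 cells that the subsampling analysis identifies as
  sufficient for a stable f_bound.
* **Bleaching.** Per-frame bleaching probability 0.2, giving bound-track
  mean length 5 frames (4 jumps) — typical for photoactivatable dyes under
  full-power excitation and consistent with ~4 jumps as the typical
  observed track length.
* **Movie sparsity.** 500 activations are spread over 5000 frames
  (~0.35 localizations/frame in a 10.24 µm field), emulating the
  low-density regime the detection/linking settings assume ("most frames
  had 1 or less"; real acquisitions spread similar trajectory counts over
  30,000 frames). Rendering at several-fold higher density measurably
  biases f_bound low through overlapping-PSF suppression and
  misconnections, so density is a study condition, not a free parameter.
* **Rendering.** Observed positions deposit pixel-integrated Gaussians
  (σ_psf = 1.2 px) scaled by a lognormal photon budget (median 500
  photons, σ_log = 0.3 — unspecified by the measurement; chosen to give
  realistic SNR at gain 109). Frames are
  `470 + 109 · Poisson(photons) + read noise`, clipped to uint16. A
  noise-free mode returns the exact expectation for oracle tests. The
  rendered movie carries the generator's localization error *and* the
  fit's own error (~0.01 µm at 500 photons); the σ grid absorbs the
  combination.
* **PAPA.** The illumination cycle is (bleach 200, image 30, green 5,
  image 30, bleach 200, image 30, violet 1, image 30) × 5 cycles; only
  imaging blocks are recorded (600 frames, 150 per epoch). All receivers
  are dark at each pulse (the 200-frame red blocks re-darken them); the
  green pulse reactivates sender-bound receivers with `p_papa_interacting`
  and others with `p_papa_background`, the violet pulse reactivates any
  receiver with `p_dr`. Reactivated molecules emit a trajectory in the
  following imaging block with the same slab/bleach kinematics.
  Reactivation probabilities are empirical inputs; no dark-state kinetics
  or distance dependence is modeled. Pre-pulse blocks contain no
  spontaneous activations, so per-cell deltas equal post-block counts;
  the delta definition (post − pre per cycle, summed) is retained because
  real data has nonzero pre-blocks.

What the generator does **not** emulate: anisotropic or astigmatic PSFs,
sCMOS pixel-dependent noise, nuclear boundaries and chromatin-density
heterogeneity, state-switching kinetics within trajectories (off by
default), sender-channel photophysics, drift. Passing recovery tests on
this generator therefore establishes the *estimator chain* is unbiased
under the stated model at the stated scale — not that real-data f_bound
values are accurate to the same tolerance.

## PAPA analysis

Recorded-frame index → epoch is pure block arithmetic
(`(i mod 120) div 30` → pre_PAPA, post_PAPA, pre_DR, post_DR; cycle =
`i div 120`). Trajectories inherit their block's epoch; a trajectory
spanning a block boundary is an upstream linking error and raises. Links
are therefore broken at block boundaries (adjacent recorded frames there
are separated by unrecorded real time). Per-cell reactivation:
`delta_papa = Σ_cycles count(post_PAPA) − count(pre_PAPA)`, likewise for
DR — localization-level statistics, invariant to linking. The
PAPA-versus-DR relation across cells is an OLS fit; its saturation
diagnostic is the Spearman correlation of residuals with delta_dr over the
**upper half** of the delta_dr range (with a fitted intercept, concave
data produce U-shaped residuals whose full-range rank correlation cancels;
saturation manifests as the high-DR tail turning negative), with a
permutation p-value. Class spectra re-run the full occupation inference
independently on PAPA- and DR-class trajectories.

## Cohort statistics

Bootstrap: B = 100 draws of n cells with replacement; each draw recomputes
the pooled, jump-weighted, defocalization-corrected f_bound from the
resampled cells' trajectories (per-cell likelihood rows are evaluated once
and shared; the per-cell-value resampling shortcut is available
separately). Condition comparison: `z = Δmean / sqrt(sd_a² + sd_b²)`,
two-tailed normal p, Šidák adjustment `1 − (1 − p)^m` with the family size
m passed explicitly (it is a property of how many comparisons are reported
together, not of the data). Degenerate zero-variance comparisons return
p = 1 (equal means) or p = 0 flagged. Subsampling draws cells first, then
trajectories, without replacement, and reports bias against the full-data
estimate — the reference an experimenter actually has. The intensity proxy
is the mean over frames of the per-frame mean pixel value of a pre-bleach
movie (optionally masked), correlated with per-cell f_bound by Pearson and
Spearman.

## Problem sizes used in tests and the acceptance script

Full-chain recovery runs 20 cells × 500 trajectories through rendered
5000-frame movies at four true bound fractions {0.10, 0.38, 0.50, 0.75};
recovery errors are within ±0.03 in all four, against a ±0.05 criterion.
The PAPA contrast experiment uses 20 cells × 2000 receivers
(interacting) and × 800 (null); subsampling uses a 24-cell × 800 cohort
subsampled down to (20 cells, 10⁴ trajectories). These sizes are the
package's validation conditions; larger cohorts only shrink the stochastic
spread.

## Known limitations

* The expected-jumps correction assumes bleaching is state-independent and
  estimates β from slow-track lengths; strongly state-dependent
  photobleaching would bias it.
* The LLR detector's exact windowing conventions follow the matched-filter
  GLRT derivation given above; other implementations of the same named
  method may differ at window edges.
* No hidden-Markov state-transition inference, anomalous-diffusion models,
  motion-blur covariance, gap closing, or drift correction — all outside
  the measurement conventions this package reproduces.
* EM point estimates are reported rather than a full posterior over
  occupations; bootstrap spread across cells is the uncertainty interface.
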