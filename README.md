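# smtpipe

A pipeline for fast single-molecule tracking (SMT) of nuclear proteins:
from raw camera movies (or simulated stand-ins) to diffusion spectra,
chromatin-bound fractions, condition comparisons, and proximity-assisted
photoactivation (PAPA) protein–protein interaction readouts.

**Who it is for.** Groups analyzing live-cell fSMT of transcription
factors and similar nuclear proteins: sparse photoactivated emitters
imaged at ~7.5 ms/frame, linked into thousands of short trajectories per
condition, summarized as the fraction of molecules bound to chromatin.

## The model at the core

A trajectory's jumps under Brownian motion with localization error (RBME)
are, per axis, multivariate normal with tridiagonal covariance

```
Σ_ll = 2 D Δt + 2σ²,   Σ_l,l+1 = −σ²
```

(D diffusion coefficient, σ localization error s.d., Δt frame interval).
Likelihoods are evaluated on a fixed grid of (D, σ) states — 100
log-spaced D in [0.01, 100] µm²/s × 6 σ in [0.02, 0.06] µm — and state
occupations θ are estimated by EM on the jump-weighted mixture likelihood

```
θ̂ = argmax Σ_i w_i log Σ_j θ_j L_ij ,
```

corrected for defocalization (fast molecules escape the 0.7 µm focal
slab) by dividing by the expected observed jumps per molecule, then
renormalizing. The marginal over σ is the *diffusion spectrum*, and

```
f_bound = Σ_{D < 0.15 µm²/s} θ_D
```

is the chromatin-bound fraction. Uncertainty comes from a cell-level
bootstrap (B = 100); conditions are compared with a two-tailed normal
test on bootstrap means with the Šidák correction. See
[docs/methods.md](docs/methods.md) for the full account, including the
LLR spot detector, the integrated-Gaussian localizer, the two linking
modes, the PAPA epoch machinery, and the synthetic-data generator.

## Worked example

Simulate two 20-cell cohorts whose ground-truth bound fractions are 0.50
("strong_binder") and 0.38 ("weak_binder"), infer spectra, bootstrap, and
compare (this is `analysis/01_simulate_cohorts.py`,
`analysis/03_diffusion_spectra.py` and
`analysis/04_condition_comparison.py` in miniature):

```python
from smtpipe import (SimState, SimulationConfig, simulate_trajectories,
                     summarize_condition, compare_conditions)

cells = {}
for label, fb, seed in [("strong_binder", 0.50, 11),
                        ("weak_binder", 0.38, 12)]:
    cfg = SimulationConfig(
        states=[SimState(D=0.02, occupancy=fb, label="bound"),
                SimState(D=3.0, occupancy=1 - fb, label="free")],
        seed=seed)                      # 20 cells x 500 trajectories
    cells[label] = simulate_trajectories(cfg, seed=seed)

a = summarize_condition("strong_binder", cells["strong_binder"], seed=31)
b = summarize_condition("weak_binder", cells["weak_binder"], seed=31)
r = compare_conditions(a, b, m=1)
```

Output of the corresponding analysis scripts:

```
strong_binder: f_bound = 0.5200 (bootstrap 0.5200 +/- 0.0105)
weak_binder:   f_bound = 0.4067 (bootstrap 0.4067 +/- 0.0064)
strong_binder vs weak_binder: delta = +0.1133, z = 9.200, p_adj = 3.6e-20 ***
```

Reading: each pooled f_bound lands within ~0.03 of its ground truth at
this cohort scale (20 cells, 10,000 trajectories — the scale the
subsampling analysis in `analysis/05_subsampling.py` identifies as
sufficient: |bias| < 0.002 and spread 0.003 at 10,000 trajectories); the
0.11 difference between conditions is highly significant against the
bootstrap spread.

The remaining drivers: `analysis/02_imaging_benchmark.py` scores
detection/localization/linking against ground truth on a rendered movie
(detection efficiency 0.81 including sub-threshold emitters, median
localization error 14 nm, no density flags), and
`analysis/06_papa_analysis.py` runs the PAPA readouts — in the simulated
interacting condition PAPA-class trajectories are substantially more
bound than DR-class (f_bound 0.685 vs 0.419) and the PAPA-vs-DR relation
is sublinear (high-DR residual trend ρ = −0.75, permutation p = 0.003),
while the non-interacting control is linear with matching class spectra.

A thin CLI mirrors the stages: `smtpipe simulate | detect | track |
spectrum | compare | subsample | papa` (see `--help`).

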