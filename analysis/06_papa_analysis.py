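#!/usr/bin/env python
"""PAPA-SMT analysis on simulated interacting and control experiments.

Simulates a proximity-interacting condition (sender-bound receivers are
mostly chromatin-bound) and a non-interacting control, then runs the full
PAPA readout chain: per-cell reactivation deltas, the PAPA-versus-DR
linear fit with its saturation diagnostic, and diffusion spectra /
f_bound per reactivation class. Writes per-condition tables under
results/.
"""

from pathlib import Path

import pandas as pd

from smtpipe.config import PAPAConfig, SimState, SimulationConfig
from smtpipe.papa import papa_dr_regression, reactivation_summary, \
    spectra_by_class
from smtpipe.simulate import simulate_papa_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"


def run_condition(label, sim, papa, seed):
    exp = simulate_papa_experiment(sim, papa, seed=seed)
    summaries = [reactivation_summary(t, exp.sequence)
                 for t in exp.cell_tables()]
    pd.DataFrame(
        [{"cell_id": s.cell_id, "delta_papa": s.delta_papa,
          "delta_dr": s.delta_dr} for s in summaries]
    ).to_csv(RESULTS / f"papa_deltas_{label}.csv", index=False)
    reg = papa_dr_regression(summaries, seed=seed)
    classes = spectra_by_class(exp.locs, exp.sequence)
    print(f"{label}: slope = {reg.slope:.3f}, R^2 = {reg.r_squared:.3f}, "
          f"high-DR residual trend rho = {reg.sublinearity_rho:+.2f} "
          f"(perm. p = {reg.sublinearity_p:.3f})")
    print(f"  f_bound PAPA = {classes['PAPA']['f_bound'].value:.3f}, "
          f"DR = {classes['DR']['f_bound'].value:.3f}, "
          f"contrast = {classes['delta_fbound']:+.3f}")
    return {
        "condition": label,
        "slope": reg.slope,
        "r_squared": reg.r_squared,
        "sublinearity_rho": reg.sublinearity_rho,
        "sublinearity_p": reg.sublinearity_p,
        "fbound_papa": classes["PAPA"]["f_bound"].value,
        "fbound_dr": classes["DR"]["f_bound"].value,
        "fbound_contrast": classes["delta_fbound"],
    }


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    bound_heavy = [SimState(0.02, 0.7, "bound"), SimState(3.0, 0.3, "free")]
    mostly_free = [SimState(0.02, 0.2, "bound"), SimState(3.0, 0.8, "free")]
    # cells vary ~6-fold in receiver expression; the interacting condition
    # has a finite sender pool, so PAPA reactivation saturates in
    # high-expressing cells while DR keeps scaling with expression
    sim = SimulationConfig(n_cells=30, traj_per_cell=600, seed=0)

    rows = [
        run_condition(
            "interacting", sim,
            PAPAConfig(frac_interacting=0.5, p_papa_interacting=0.5,
                       p_papa_background=0.02, p_dr=0.15,
                       cell_size_range=(0.3, 1.7), sender_pool=300,
                       states_interacting=bound_heavy,
                       states_free=mostly_free),
            seed=51,
        ),
        run_condition(
            "control", sim,
            PAPAConfig(frac_interacting=0.0, p_papa_interacting=0.02,
                       p_papa_background=0.02, p_dr=0.15,
                       cell_size_range=(0.3, 1.7),
                       states_interacting=mostly_free,
                       states_free=mostly_free),
            seed=52,
        ),
    ]
    pd.DataFrame(rows).to_csv(RESULTS / "papa_summary.csv", index=False)


if __name__ == "__main__":
    main()
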