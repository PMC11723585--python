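#!/usr/bin/env python
"""Bootstrap spreads and pairwise comparison of the simulated conditions.

Cell-level bootstrap (B = 100) of the pooled f_bound per condition, then
the two-tailed normal comparison with Sidak correction. Writes
results/condition_comparison.csv. Run 01 first.
"""

from pathlib import Path

import pandas as pd

from smtpipe import io as pio
from smtpipe.pipeline import cells_from_linked_tables
from smtpipe.spectrum import DiffusionGrid
from smtpipe.stats import compare_conditions, summarize_condition

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    grid = DiffusionGrid()
    summaries = []
    for path in sorted(SCRATCH.glob("trajs_*.csv")):
        label = path.stem.replace("trajs_", "")
        table = pio.load_trajectories(path)
        cells = cells_from_linked_tables(
            [sub for _, sub in table.groupby("cell_id", sort=True)]
        )
        s = summarize_condition(label, cells, B=100, seed=31, grid=grid)
        summaries.append(s)
        print(f"{label}: f_bound = {s.pooled_fbound:.4f} "
              f"(bootstrap {s.bootstrap_mean:.4f} +/- {s.bootstrap_sd:.4f})")
    pairs = [(i, j) for i in range(len(summaries))
             for j in range(i + 1, len(summaries))]
    rows = []
    for i, j in pairs:
        r = compare_conditions(summaries[i], summaries[j], m=len(pairs))
        rows.append(vars(r))
        print(f"{r.label_a} vs {r.label_b}: delta = {r.delta:+.4f}, "
              f"z = {r.z:.3f}, p_adj = {r.p_adjusted:.3g} {r.stars}")
    pd.DataFrame(rows).to_csv(RESULTS / "condition_comparison.csv",
                              index=False)


if __name__ == "__main__":
    main()
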