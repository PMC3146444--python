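"""Hybrid-class calibration: simulated crosses through the admixture model.

Generates the seven cross categories (F1, F2, graellsii backcross, four
elegans backcrosses) from two differentiated parental pools, estimates
every simulated individual's ancestry with the supervised admixture model,
and calibrates the ancestry bins: which interval of q each cross occupies.
Scaled down (25 per cross, short chains) to run in under a minute.
"""

import numpy as np
import pandas as pd

from introgress import (
    AdmixtureConfig,
    balding_nichols_freqs,
    calibrate_bins,
    concat_tables,
    generate_cross_panel,
    run_admixture,
    simulate_genotypes,
)

ancestral = [{a: 0.1 for a in range(1, 11)} for _ in range(6)]
gf, ef = balding_nichols_freqs(ancestral, theta=0.2, n_pops=2, seed=0)
g = simulate_genotypes(gf, 50, seed=1, population="G", species="graellsii",
                       is_reference=True)
e = simulate_genotypes(ef, 50, seed=2, population="E", species="elegans",
                       is_reference=True)

panel = generate_cross_panel(g, e, n_per_cross=25, mode="frequency_draw", seed=3)
crosses = panel.to_table()
table = concat_tables([g, e, crosses])

cfg = AdmixtureConfig(K=2, burn_in=2000, n_sweeps=8000,
                      use_reference_labels=True, seed=4)
run = run_admixture(table, cfg)

ids = [s.id for s in crosses.samples]
df = pd.DataFrame({
    "cross": [s.population for s in crosses.samples],
    "q_elegans": run.q_mean.loc[ids, "cluster_1"].to_numpy(),
})
report = calibrate_bins(df)
print(report.round(3).to_string())
print("\nexpected ancestry per cross:",
      {c.value: c.expected_elegans_ancestry for c in panel.panels})
# q_mean should rise along GB1 < F1 ~ F2 < EB1 < EB2 < EB3 < EB4, and the
# bin counts show which assignment groups each cross category occupies —
# the calibration that justifies reading backcross status off q intervals.
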