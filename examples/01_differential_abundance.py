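"""Run all six differential-abundance tests on one simulated dataset.

Simulates a 120-taxon, 25-samples-per-group experiment in which 10% of the
taxa differ fivefold between groups, selects a reference frame
automatically, and applies each sign-based procedure.  The printed table
shows, per method, how many taxa were called at the 5% FDR level and how
many of those calls are correct against the simulation truth.
"""

import pandas as pd

from signda import (
    METHODS,
    SimulationConfig,
    run_all_taxa,
    select_reference_frame,
    simulate_dataset,
    trim_low_prevalence,
)

data = simulate_dataset(
    SimulationConfig(n_taxa=120, n_per_group=25, fold_change=5.0,
                     da_fraction=0.10, seed=1)
)
table = trim_low_prevalence(data.table, 0.05)  # drop taxa seen in <5% of samples
meta = data.meta.aligned_to(table.sample_ids)
rf = select_reference_frame(table, meta)
print(f"{table.n_taxa} taxa after trimming; reference frame: {', '.join(rf.taxa)}")

rows = []
for method in METHODS:
    res = run_all_taxa(table, meta, rf, method, alpha=0.05)
    called = res.loc[res["discovery"], "taxon_id"]
    correct = int(data.truth.reindex(called).sum())
    rows.append({"method": method, "discoveries": len(called), "true": correct})
print(pd.DataFrame(rows).to_string(index=False))
print(
    "\n'discoveries' are taxa with BH-adjusted p <= 0.05; 'true' counts how many"
    "\nare genuinely differentially abundant in the simulation truth."
)
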