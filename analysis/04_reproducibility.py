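#!/usr/bin/env python
"""Between-run reproducibility of the position-12 dispersal time.

Feeds the published per-run dispersal-time summaries (mean +/- sample SD
over areas a-c at position 12, one pair of runs per flow rate) through
the reproducibility statistics, and complements them with a synthetic
two-run comparison produced by the pipeline itself.  Writes
results/reproducibility.csv.
"""

from pathlib import Path

from biofilm_flowcell.experiments import recovery_experiment
from biofilm_flowcell.kinetics import reproducibility_row, reproducibility_table

OUT = Path("results")
OUT.mkdir(exist_ok=True)

# published run summaries: (mean, sd) minutes at position 12, areas a-c
published = {
    0.1: ((370.0, 6.0), (387.0, 0.0)),
    0.5: ((432.0, 6.0), (438.0, 0.0)),
    1.5: ((472.0, 6.0), (468.0, 0.0)),
    4.0: ((539.0, 10.0), None),
}

rows = [reproducibility_row(q, r1, r2) for q, (r1, r2) in published.items()]
table = reproducibility_table(rows)
table.to_csv(OUT / "reproducibility.csv", index=False)
print(table.to_string(index=False))
print("finding: between-run dispersal-time differences are 4-17 min "
      "(0.8-4.6 % of the run mean) and within-run variation across the "
      "three replicate areas is <= 1.9 %.")

# synthetic two-run check: same conditions, different seeds
d1 = recovery_experiment(101, noise=True)
d2 = recovery_experiment(202, noise=True)
o1 = d1.loc[d1.x_location == 12, "detected_onset_min"].iloc[0]
o2 = d2.loc[d2.x_location == 12, "detected_onset_min"].iloc[0]
print(f"synthetic replicate runs detect position-12 onset at {o1:.0f} and "
      f"{o2:.0f} min (|delta| = {abs(o1 - o2):.0f} min), consistent with "
      "the minutes-scale repeatability above.")
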