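"""Simulate a synthetic preterm/term DTI study and write its CSV files.

Generates the default cohort (43 preterm infants, GAB 23.7-36.9 weeks;
43 term infants, GAB 38.0-41.6 weeks; scans near 43 weeks PMA) and 126
RD regions of which six carry planted change-points, then writes
cohort.csv, metrics.csv and truth.csv.
"""

from neurocp import SimCohortSpec, rd_study_region_specs, simulate_study

paths = simulate_study(SimCohortSpec(seed=1), rd_study_region_specs(),
                       "scratch/example_study")

import pandas as pd

cohort = pd.read_csv(paths["cohort"])
print(f"wrote {', '.join(str(p) for p in paths.values())}")
print(f"{len(cohort)} subjects "
      f"({(cohort.group == 'preterm').sum()} preterm, "
      f"{(cohort.group == 'term').sum()} term)")
print(f"GAB range {cohort.gab.min():.1f}-{cohort.gab.max():.1f} wk, "
      f"PMA mean {cohort.pma.mean():.1f} wk, "
      f"{cohort.sex.sum()} male / {(1 - cohort.sex).sum()} female")
# GAB spans both groups' ranges; PMA clusters tightly around scan age, so
# birth timing (GAB) and brain maturity at scan (PMA) are separable.
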