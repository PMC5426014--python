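"""Whole-brain change-point analysis with familywise control.

Simulates the 126-region RD study (six planted change-points), runs
every region through profile fit + permutation test + bootstrap, applies
max-statistic familywise correction across the 126 regions, and prints
the regions surviving familywise alpha = 0.05.
"""

from neurocp import (AnalysisConfig, SimCohortSpec, rd_study_region_specs,
                     read_cohort, read_region_metrics, run_all_regions,
                     significant_regions, simulate_study, write_results)

paths = simulate_study(SimCohortSpec(seed=1), rd_study_region_specs(),
                       "scratch/example_study")
cohort = read_cohort(paths["cohort"])
sets = read_region_metrics(paths["metrics"], cohort)

config = AnalysisConfig(B=199, B_boot=100, seed=2)
results = run_all_regions(cohort, sets, config)
write_results(results, "scratch/example_study/results.csv")

sig = significant_regions(results, alpha=0.05)
print(f"{len(sig)} of {len(results)} regions significant at "
      "familywise p < 0.05 (earliest change-point first):")
print(sig[["region_id", "region_name", "delta_hat", "delta_sd",
           "p_raw", "p_familywise", "pattern"]].to_string(index=False))
# Only regions whose change-point statistic beats the permutation
# distribution of the across-region maximum survive; their delta_hat
# values recover the planted 31-34 week change-points.
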