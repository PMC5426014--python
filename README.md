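# neurocp

Change-point regression of regional neonatal brain MRI metrics against
gestational age at birth (GAB).

Preterm birth interrupts brain development, and the consequences depend on
*when* in gestation the interruption happens. Given a cross-sectional cohort
of preterm- and term-born infants scanned as neonates, `neurocp` asks, for
every brain region: at which gestational age at birth does the trajectory of
a diffusion-tensor metric (FA, MD, AD or RD) change slope? The package is
written for researchers running regional change-point analyses of this kind
— it provides the regression core, resampling inference, a whole-brain
driver with familywise control, and a synthetic-cohort generator so that
every stage can be validated without access to clinical data.

## Model

For one region and metric, with subject index $k$:

$$y_k = a_0 + a_1 g_k + a_2 (g_k - \Delta)\,H(g_k - \Delta) + a_3 p_k + a_4 s_k + \epsilon_k$$

where $g_k$ is GAB (weeks), $p_k$ postmenstrual age at scan (weeks), $s_k$
binary sex, and $H(x) = 1$ iff $x > 0$ (strict). The trajectory is piecewise
linear and continuous in $g$: slope $a_1$ before the change-point $\Delta$
and $a_1 + a_2$ after it. $\Delta$ is estimated by minimising the residual
sum of squares over a candidate grid (default 24.0–36.5 weeks in 0.1-week
steps, keeping at least 5 subjects strictly on each side).

Inference propagates the grid search everywhere it matters:

* **Permutation test** (Freedman–Lane): the reduced model without the hinge
  term is fitted, its residuals are permuted and added back, and the *full
  search* is re-run per permutation; `p_raw = (1 + #{null ≥ obs})/(B + 1)`.
* **Bootstrap SD of Δ**: subjects are resampled with replacement and the
  search re-run per resample.
* **Familywise control**: all regions of a metric share the same permutation
  shuffles, and each region is compared against the distribution of the
  across-region *maximum* statistic (Bonferroni available as fallback).

## Worked example

```python
from neurocp import (DeltaGridSpec, SimCohortSpec, SimRegionSpec,
                     make_delta_grid, profile_changepoint,
                     simulate_cohort, simulate_region)

cohort = simulate_cohort(SimCohortSpec(seed=1))    # 43 preterm + 43 term
spec = SimRegionSpec(region_id=1, metric="RD", pattern="rise_plateau",
                     delta_true=31.0, a0=5.0, pre_slope=-0.09,
                     post_slope=0.0, pma_slope=-0.01, sex_effect=0.02,
                     noise_sd=0.06)
y = simulate_region(cohort, spec, seed=2).values
fit = profile_changepoint(cohort, y, make_delta_grid(cohort, DeltaGridSpec()))
print(fit.delta_hat, fit.pre_slope, fit.post_slope)
```

prints (see `examples/02_single_region_fit.py`):

```
true change-point: 31.0 wk   estimated: 31.5 wk
pre-change slope  a1      = -0.0807 per wk (truth -0.0900)
post-change slope a1 + a2 = +0.0014 per wk (truth +0.0000)
```

i.e. the region's radial diffusivity falls by ~0.08×10⁻³ mm²/s per
gestational week for births before ~31 weeks and is flat for later births —
the estimated break sits half a week from the planted one. The whole-brain
driver (`examples/04_whole_brain_study.py`) runs 126 such regions, six with
planted change-points, and returns exactly those six at familywise
p < 0.05 with change-points at 30–35 weeks.

The other `examples/` scripts cover study simulation, permutation +
bootstrap inference, and re-fitting AD/RD at an FA-derived change-point.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates the default synthetic study from scratch, runs the complete
whole-brain analysis (fits, permutation p-values, familywise correction,
bootstrap SDs), writes the per-region results CSV next to the JSON output,
and prints the significant regions.
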