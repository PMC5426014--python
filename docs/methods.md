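# Methods

## The model and its estimation

Each (region, metric) pair is modelled as a continuous piecewise-linear
("broken-stick") function of gestational age at birth (GAB, $g$), with
postmenstrual age at scan ($p$) and sex ($s$) as nuisance covariates:

$$y_k = a_0 + a_1 g_k + a_2 (g_k-\Delta) H(g_k-\Delta) + a_3 p_k + a_4 s_k + \epsilon_k,
\qquad \epsilon_k \sim N(0, \sigma^2) \text{ i.i.d.}$$

$H$ is the *strict* indicator ($H(0)=0$). The event $g_k=\Delta$ has
probability zero for continuous GAB; fixing the convention keeps results
reproducible. The hinge regressor makes the fitted trajectory continuous at
$\Delta$ by construction; $a_1$ is the pre-change slope and $a_1+a_2$ the
post-change slope.

For fixed $\Delta$ the model is linear and fitted by ordinary least
squares. $\Delta$ itself is profiled: the RSS is evaluated on an arithmetic
candidate grid and the minimiser taken. The implementation factorises each
candidate design once (batched QR) and obtains the RSS of any response from
the factorisation, which is what makes re-searching $\Delta$ inside every
permutation and bootstrap resample affordable; the test-suite cross-checks
it against a from-scratch refit at every candidate.

Numerical conventions:

* responses are centred before RSS profiling (the intercept absorbs the
  shift), which keeps the $\|y\|^2-\|Q^\top y\|^2$ cancellation error on the
  residual scale and makes the profile invariant to adding constants to $y$;
* RSS ties (within $10^{-8}$ relative plus a cancellation floor) are broken
  toward the smallest $\Delta$ — in particular a truly linear trajectory
  deterministically yields the first grid point;
* candidates whose design is rank deficient (QR diagonal below $10^{-9}$
  relative) are excluded from the profile; if all are, the region is
  reported as unfittable rather than fitted by pseudo-inverse.

## Candidate grid

Default 24.0–36.5 weeks in 0.1-week steps, keeping only candidates with at
least `min_per_side = 5` subjects strictly on each side. The search spans
the preterm GAB range — a change-point outside it is not identifiable from
a design in which term births cluster within 3.6 weeks — and the 0.1-week
step matches the precision at which change-points are conventionally
reported. Grid bounds, step and `min_per_side` are all configurable
(`DeltaGridSpec`).

## Permutation test

The hypothesis "no change-point" is the reduced model $a_2=0$. The test
statistic is the F-like improvement
$\big(RSS_{reduced}-RSS_{full}(\hat\Delta)\big) / \big(RSS_{full}(\hat\Delta)/(n-5)\big)$
with the full-model RSS minimised over the grid. No F reference
distribution is used — the extra degrees of freedom spent selecting
$\Delta$ are accounted for by re-running the selection inside the null:
following the Freedman–Lane scheme, reduced-model residuals are permuted
among subjects, added back to the reduced fitted values, and the complete
profile search is repeated per permutation. This keeps the nuisance
structure (intercept, linear GAB trend, PMA, sex) intact under the null.
The add-one estimator $p=(1+\#\{T^{null}\ge T\})/(B+1)$ makes $p$ valid at
finite $B$; its support is $\{1/(B+1),\dots,1\}$. When the full model fits
exactly ($RSS_{full}$ below $10^{-14}\times$ the centred sum of squares),
the statistic is capped at a sentinel ($10^{12}$) so comparisons remain
well-defined. Default $B=1000$.

## Bootstrap SD of the change-point

Case resampling: subjects are drawn with replacement (n unchanged;
optionally within preterm/term strata via `stratified=True` — the default
is unstratified), and the full profile search re-run per resample. The
reported `delta_sd` is the sample SD over successful resamples. A resample
can fail when its GAB distribution leaves no candidate with enough subjects
on both sides; failures are counted and more than 50% aborts with an
error. Default 1000 resamples. At the calibration point used in the
acceptance suite (slope change of 1.5 noise SDs per week, n = 86) the
bootstrap SD is required to track the Monte-Carlo sampling SD of
$\hat\Delta$ within 35%; grid-argmin estimators are discrete, so closer
agreement should not be expected in general.

## Familywise control

All regions of one metric are tested with the *same* subject shuffles; the
familywise p of region $r$ compares its observed statistic against the
permutation distribution of $\max_r T^{null}_{b,r}$. This controls the
FWER while adapting to inter-region correlation, and is never materially
more conservative than Bonferroni (which is available as a fallback for
results produced with unshared shuffles). Correction is applied within
each metric separately — AD over its regions, RD over its — mirroring how
per-metric whole-brain analyses are reported; no correction is applied
across metrics. Regions with missing subjects reuse the full-cohort
shuffle compressed to their observed subset (rank-order restriction);
sharing is exact whenever regions have identical subject sets, which is
the synthetic default.

## Pattern classification

With pre-slope $a_1$ and post-slope $a_1+a_2$ and a tolerance `tol`:
`rise_plateau` if $a_1>$ tol and $|a_1+a_2|\le$ tol; `plateau_decline` if
$|a_1|\le$ tol and $a_1+a_2<-$tol; otherwise `other`. The pipeline sets
`tol` to 25% of the larger absolute segment slope — the two templates are
qualitative, so an absolute threshold in metric units would be arbitrary
across metrics. Note a *decline*-then-plateau region (common for
diffusivities, which fall with maturation) is labelled `other`; the two
named templates describe FA-style trajectories.

## Synthetic data: what it does and does not emulate

`simulate_cohort` reproduces the stated study design: 43 preterm subjects
with GAB uniform on [23.7, 36.9] weeks, 43 term on [38.0, 41.6], PMA
Gaussian (mean 43, SD 1 week) truncated above the maximum term GAB so every
scan postdates every birth, sex Bernoulli with the pooled male fraction
45/86. GAB is uniform within its range because only ranges are stated;
PMA is independent of GAB by default (scans happened "around 43 weeks"
regardless of birth timing). `simulate_region` draws from the analysis
model itself with homoscedastic Gaussian noise; the default RD study
template plants six signals (31–34 weeks, slope change 1.5 noise-SDs per
week, noise SD 0.06 ×10⁻³ mm²/s) among 120 null regions with a shared
slow linear decline.

Because generator and analysis share the same model family, green
simulation tests establish *internal* correctness — estimator consistency,
test calibration, FWER control — not robustness to real-data violations:
heteroscedastic or heavy-tailed noise, GAB-dependent scan timing,
non-linear maturation within a phase, or spatial correlation between
regions (except where the FWER test injects equicorrelated noise
deliberately).

## Determinism and seeds

All randomness flows from integer seeds through numpy `SeedSequence`
spawning with fixed purpose keys: per-metric keys for the shared
permutation shuffles, data-content keys (CRC32 of the response vector) for
per-region bootstrap streams. Consequently identical (config, seed) give
byte-identical results CSVs, results do not depend on region execution
order, and relabelling region ids permutes rows without changing any
number.

## Known limitations

* One change-point per region; no smooth alternatives or mixed effects.
* The permutation and familywise schemes are standard choices for this
  class of problem, selected and documented here; other defensible schemes
  (e.g. sign-flipping, FDR) are not implemented.
* Bootstrap SD of a grid-argmin estimator inherits the grid's
  discreteness; with very strong signals it can collapse to 0.
* FA values are clipped to [0, 1] at generation when the linear model
  strays outside; heavy clipping would bias recovery (a warning is
  emitted).
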