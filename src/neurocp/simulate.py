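"""Synthetic two-group neonatal cohorts and regional DTI trajectories.

The generator emulates the study design the analysis assumes: 43 preterm
infants with GAB uniform on 23.7–36.9 weeks and 43 term infants on
38.0–41.6 weeks, all scanned near a postmenstrual age of 43 weeks, with
binary sex. Each region's metric follows the analysis model itself — two
linear GAB phases joined at a true change-point, plus linear PMA and sex
terms and homoscedastic Gaussian noise — so every pipeline stage can be
exercised against known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort_io import (CohortTable, RegionMetricSet, write_cohort,
                        write_region_metrics)
from .core import hinge
from .errors import ConfigurationError, ValidationError

#: pooled male fraction of the study cohort (24/43 preterm + 21/43 term)
DEFAULT_SEX_BALANCE = 45.0 / 86.0


@dataclass(frozen=True)
class SimCohortSpec:
    """Cohort design parameters; defaults mirror the study population."""

    n_preterm: int = 43
    n_term: int = 43
    gab_preterm_range: tuple[float, float] = (23.7, 36.9)
    gab_term_range: tuple[float, float] = (38.0, 41.6)
    pma_mean: float = 43.0
    pma_sd: float = 1.0
    sex_balance: float = DEFAULT_SEX_BALANCE
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.gab_preterm_range, self.gab_term_range):
            if not 0 < lo < hi:
                raise ConfigurationError("GAB ranges must be ordered and positive")
        if self.n_preterm < 0 or self.n_term < 0 or self.n_preterm + self.n_term == 0:
            raise ConfigurationError("need a positive total number of subjects")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ConfigurationError("sex_balance is a proportion")


@dataclass(frozen=True)
class SimRegionSpec:
    """Ground-truth trajectory for one (region, metric).

    ``pattern`` is the intended qualitative template; the slopes define
    the trajectory. ``null`` forces a single linear phase
    (pre_slope == post_slope, change-point absent by construction).
    """

    region_id: int
    metric: str
    pattern: str = "null"
    delta_true: float = 30.0
    a0: float = 0.0
    pre_slope: float = 0.0
    post_slope: float = 0.0
    pma_slope: float = 0.0
    sex_effect: float = 0.0
    noise_sd: float = 0.0
    region_name: str = ""

    def __post_init__(self) -> None:
        if self.pattern not in ("rise_plateau", "plateau_decline", "null"):
            raise ConfigurationError(f"unknown pattern '{self.pattern}'")
        if self.pattern == "null" and self.pre_slope != self.post_slope:
            raise ValidationError("null pattern requires pre_slope == post_slope")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not self.region_name:
            object.__setattr__(self, "region_name",
                               f"region_{self.region_id:03d}")


def simulate_cohort(spec: SimCohortSpec) -> CohortTable:
    """Draw a cohort: GAB uniform within each group's range, PMA truncated
    Gaussian above the maximum term GAB (every scan postdates every birth),
    sex Bernoulli(sex_balance). Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo_p, hi_p = spec.gab_preterm_range
    lo_t, hi_t = spec.gab_term_range
    gab = np.concatenate([rng.uniform(lo_p, hi_p, spec.n_preterm),
                          rng.uniform(lo_t, hi_t, spec.n_term)])
    a = (hi_t - spec.pma_mean) / spec.pma_sd
    pma = stats.truncnorm.rvs(a, np.inf, loc=spec.pma_mean, scale=spec.pma_sd,
                              size=gab.size, random_state=rng)
    sex = (rng.random(gab.size) < spec.sex_balance).astype(int)
    ids = ([f"P{i + 1:03d}" for i in range(spec.n_preterm)]
           + [f"T{i + 1:03d}" for i in range(spec.n_term)])
    group = ["preterm"] * spec.n_preterm + ["term"] * spec.n_term
    return CohortTable(np.array(ids, dtype=object), gab, pma, sex,
                       np.array(group, dtype=object))


def simulate_region(cohort: CohortTable, spec: SimRegionSpec,
                    seed=0) -> RegionMetricSet:
    """Generate one region's metric from the change-point model itself.

    y = a0 + pre_slope*g + (post_slope - pre_slope)*hinge(g, delta_true)
        + pma_slope*p + sex_effect*s + N(0, noise_sd^2).

    FA values are clipped to [0, 1] (with a warning) since the linear
    model has unbounded range.
    """
    if spec.pattern != "null":
        if not cohort.gab.min() < spec.delta_true < cohort.gab.max():
            raise ConfigurationError(
                f"delta_true={spec.delta_true} lies outside the cohort GAB range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a2 = spec.post_slope - spec.pre_slope
    mean = (spec.a0 + spec.pre_slope * cohort.gab
            + a2 * hinge(cohort.gab, spec.delta_true)
            + spec.pma_slope * cohort.pma + spec.sex_effect * cohort.sex)
    y = mean + (rng.normal(0.0, spec.noise_sd, cohort.n)
                if spec.noise_sd > 0 else 0.0)
    if spec.metric == "FA" and ((y < 0) | (y > 1)).any():
        warnings.warn(f"region {spec.region_id}: FA values clipped to [0, 1]",
                      stacklevel=2)
        y = np.clip(y, 0.0, 1.0)
    return RegionMetricSet(spec.region_id, spec.region_name, spec.metric, y)


def rd_study_region_specs(n_regions: int = 126, n_signal: int = 6,
                          effect: float = 1.5, noise_sd: float = 0.06
                          ) -> list[SimRegionSpec]:
    """126-region RD study template: six planted change-points, rest null.

    The planted regions mimic the reported RD findings — bilateral pons
    near 31 weeks, right gyrus rectus at 33, bilateral PLIC and left
    globus pallidus at 34 — five declining then plateauing and one
    plateauing then declining. ``effect`` is the slope change in noise-SD
    units per week (|a2| = effect * noise_sd).
    """
    a2 = effect * noise_sd
    planted = [
        ("pons_l", 31.0, -a2, 0.0), ("pons_r", 31.0, -a2, 0.0),
        ("gyrus_rectus_r", 33.0, 0.0, -a2), ("plic_l", 34.0, -a2, 0.0),
        ("plic_r", 34.0, -a2, 0.0), ("globus_pallidus_l", 34.0, -a2, 0.0),
    ][:n_signal]
    specs: list[SimRegionSpec] = []
    for rid in range(1, n_regions + 1):
        if rid <= len(planted):
            name, delta, pre, post = planted[rid - 1]
            pattern = ("plateau_decline" if pre == 0.0 else "rise_plateau")
            specs.append(SimRegionSpec(
                region_id=rid, metric="RD", pattern=pattern, delta_true=delta,
                a0=5.0, pre_slope=pre, post_slope=post, pma_slope=-0.01,
                sex_effect=0.02, noise_sd=noise_sd, region_name=name))
        else:
            specs.append(SimRegionSpec(
                region_id=rid, metric="RD", pattern="null", delta_true=30.0,
                a0=3.0, pre_slope=-0.02, post_slope=-0.02, pma_slope=-0.01,
                sex_effect=0.02, noise_sd=noise_sd))
    return specs


def fa_pattern_spec(region_id: int, pattern: str, delta_true: float = 30.0,
                    noise_sd: float = 0.02) -> SimRegionSpec:
    """FA trajectory for one of the two qualitative templates.

    rise_plateau: FA climbs ~0.008/week before the change-point then
    flattens; plateau_decline: flat before, falls ~0.008/week after.
    Magnitudes sit in the observed neonatal FA range.
    """
    if pattern == "rise_plateau":
        pre, post, a0 = 0.008, 0.0, 0.08
    elif pattern == "plateau_decline":
        pre, post, a0 = 0.0, -0.008, 0.55
    else:
        raise ConfigurationError(f"no FA template for pattern '{pattern}'")
    return SimRegionSpec(region_id=region_id, metric="FA", pattern=pattern,
                         delta_true=delta_true, a0=a0, pre_slope=pre,
                         post_slope=post, pma_slope=0.002, sex_effect=0.01,
                         noise_sd=noise_sd)


def _region_seed(root_seed: int, spec: SimRegionSpec) -> np.random.SeedSequence:
    metric_code = {"FA": 0, "MD": 1, "AD": 2, "RD": 3}[spec.metric]
    return np.random.SeedSequence(root_seed,
                                  spawn_key=(7, spec.region_id, metric_code))


def simulate_study(cohort_spec: SimCohortSpec,
                   region_specs: list[SimRegionSpec], out_dir) -> dict:
    """Simulate a whole study and write cohort.csv, metrics.csv, truth.csv.

    Region noise streams are derived from ``cohort_spec.seed`` by a
    counter-based spawn, so output is byte-identical across reruns and
    independent of region order. truth.csv records the planted parameters
    for downstream recovery checks.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cohort_spec)
    sets = [simulate_region(cohort, s,
                            np.random.default_rng(_region_seed(cohort_spec.seed, s)))
            for s in region_specs]
    paths = {"cohort": out / "cohort.csv", "metrics": out / "metrics.csv",
             "truth": out / "truth.csv"}
    write_cohort(cohort, paths["cohort"])
    write_region_metrics(sets, cohort, paths["metrics"])
    truth = pd.DataFrame([asdict(s) for s in region_specs])
    truth.to_csv(paths["truth"], index=False)
    return paths


def load_sim_config(path) -> tuple[SimCohortSpec, list[SimRegionSpec]]:
    """Read a YAML study description: a `cohort` mapping plus a `regions` list."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cohort_cfg = dict(cfg.get("cohort", {}))
    for key in ("gab_preterm_range", "gab_term_range"):
        if key in cohort_cfg:
            cohort_cfg[key] = tuple(cohort_cfg[key])
    cohort_spec = SimCohortSpec(**cohort_cfg)
    regions = [SimRegionSpec(**r) for r in cfg.get("regions", [])]
    return cohort_spec, regions
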