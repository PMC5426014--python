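"""Whole-brain driver: fit every (region, metric), control familywise error,
classify trajectory patterns, and export figure-style panel data.

Familywise correction is performed within each metric (all regions of one
metric share one set of permutation shuffles, so the max-statistic
distribution adapts to inter-region correlation); metrics are corrected
independently of each other.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort_io import CohortTable, METRICS, RegionMetricSet
from .core import (ChangePointFit, DeltaGridSpec, adjust_covariates,
                   fit_fixed_delta, gab_trend_values, make_delta_grid)
from .errors import (ConfigurationError, InsufficientDataError, NoFitError,
                     UnstableBootstrapError, ValidationError)
from .inference import (ProfileEngine, bootstrap_delta_sd, changepoint_stat,
                        draw_permutations, familywise_adjust,
                        permutation_null_stats)

logger = logging.getLogger("neurocp")

_METRIC_CODE = {m: i for i, m in enumerate(METRICS)}

PATTERNS = ("rise_plateau", "plateau_decline", "other")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the whole-brain analysis.

    ``slope_tol_frac`` sets the pattern-classification tolerance as a
    fraction of the larger absolute segment slope (the patterns are
    qualitative, so the threshold is relative).
    """

    grid: DeltaGridSpec = field(default_factory=DeltaGridSpec)
    B: int = 1000
    B_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0
    familywise: str = "maxstat"
    stratified_bootstrap: bool = False
    slope_tol_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ConfigurationError("need at least one permutation (B >= 1)")
        if self.B_boot < 2:
            raise ConfigurationError("need at least two bootstrap resamples")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must be in (0, 1]")
        if self.familywise not in ("maxstat", "bonferroni"):
            raise ConfigurationError(
                f"unknown familywise method '{self.familywise}'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        grid = DeltaGridSpec(**cfg.pop("grid", {}))
        return cls(grid=grid, **cfg)


def classify_pattern(fit: ChangePointFit, slope_tol: float) -> str:
    """Label the trajectory by its segment slopes.

    rise_plateau: clearly positive pre-change slope, near-zero after;
    plateau_decline: near-zero before, clearly negative after; anything
    else is ``other``. ``slope_tol`` is the absolute per-week threshold
    separating "near-zero" from "clear".
    """
    pre, post = fit.pre_slope, fit.post_slope
    if pre > slope_tol and abs(post) <= slope_tol:
        return "rise_plateau"
    if abs(pre) <= slope_tol and post < -slope_tol:
        return "plateau_decline"
    return "other"


def _relative_slope_tol(fit: ChangePointFit, frac: float) -> float:
    return frac * max(abs(fit.pre_slope), abs(fit.post_slope))


def _restrict_perms(perms: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Compress full-cohort shuffles onto a region's observed subset.

    Keeps the relative order the full shuffle induces among observed
    subjects, so regions with (few) missing values still share the
    familywise shuffles as closely as possible.
    """
    if observed.all():
        return perms
    local = np.full(observed.size, -1)
    local[np.flatnonzero(observed)] = np.arange(int(observed.sum()))
    keep = observed[perms]                       # (B, n) bool, m True per row
    return local[perms[keep]].reshape(perms.shape[0], int(observed.sum()))


def _content_key(y: np.ndarray) -> int:
    return zlib.crc32(np.ascontiguousarray(y).tobytes())


def _null_row(s: RegionMetricSet) -> dict:
    return {
        "region_id": s.region_id, "region_name": s.region_name,
        "metric": s.metric, "delta_hat": np.nan,
        "a0": np.nan, "a1": np.nan, "a2": np.nan, "a3": np.nan, "a4": np.nan,
        "rss": np.nan, "p_raw": np.nan, "p_familywise": np.nan,
        "delta_sd": np.nan, "pattern": "other", "n_used": s.n_observed,
        "status": "no_fit",
    }


def run_all_regions(cohort: CohortTable, metric_sets: list[RegionMetricSet],
                    config: AnalysisConfig,
                    null_stats_dir=None) -> pd.DataFrame:
    """Run the full change-point analysis over every (region, metric).

    Per region: profile fit, Freedman–Lane permutation p, bootstrap SD of
    the change-point, pattern label; then familywise correction across the
    regions of each metric (shuffles shared within metric). Deterministic
    given (config, seed) and independent of region order: permutation
    streams are keyed by metric and bootstrap streams by the region's data
    content, not by position.

    ``null_stats_dir``, if given, receives one compressed CSV of null
    statistics per metric so the familywise step can be replayed.
    """
    if not metric_sets:
        raise ValidationError("metric_sets is empty")
    rows: list[dict] = []
    order = sorted(metric_sets, key=lambda s: (s.metric, s.region_id))
    for metric in sorted({s.metric for s in order}):
        sets = [s for s in order if s.metric == metric]
        perms_full = draw_permutations(
            cohort.n, config.B,
            np.random.SeedSequence(config.seed,
                                   spawn_key=(11, _METRIC_CODE[metric])))
        engines: dict[bytes, ProfileEngine] = {}
        stats_obs, null_cols, ok_rows = [], [], []
        for s in sets:
            t0 = time.perf_counter()
            try:
                row = _fit_one_region(cohort, s, config, perms_full, engines)
            except (NoFitError, ConfigurationError, InsufficientDataError,
                    UnstableBootstrapError) as exc:
                logger.info("region %s/%s: no fit (%s)", metric, s.region_id, exc)
                rows.append(_null_row(s))
                continue
            row, stat_obs, nulls = row
            stats_obs.append(stat_obs)
            null_cols.append(nulls)
            ok_rows.append(len(rows))
            rows.append(row)
            logger.info(
                "region %s/%s: delta=%.2f p_raw=%.4g n=%d (%.2fs, seed=%d)",
                metric, s.region_id, row["delta_hat"], row["p_raw"],
                row["n_used"], time.perf_counter() - t0, config.seed)
        if ok_rows:
            null_matrix = np.column_stack(null_cols)
            fw = familywise_adjust(np.asarray(stats_obs), null_matrix,
                                   method=config.familywise)
            for j, i in enumerate(ok_rows):
                rows[i]["p_familywise"] = float(fw.p_fwe_by_region[j])
            if null_stats_dir is not None:
                _save_null_stats(null_stats_dir, metric, null_matrix,
                                 [rows[i]["region_id"] for i in ok_rows])
    return pd.DataFrame(rows)


def _fit_one_region(cohort, s, config, perms_full, engines):
    sub, y = s.complete_case(cohort)
    grid = make_delta_grid(sub, config.grid)
    key = s.observed.tobytes()
    if key not in engines:
        engines[key] = ProfileEngine(sub, grid)
    engine = engines[key]
    perms = _restrict_perms(perms_full, s.observed)
    stat_obs, nulls = permutation_null_stats(sub, y, grid, perms, engine=engine)
    _, fit = changepoint_stat(sub, y, grid)
    p_raw = (1.0 + np.count_nonzero(nulls >= stat_obs)) / (config.B + 1.0)
    boot_seed = np.random.SeedSequence(
        config.seed, spawn_key=(13, _METRIC_CODE[s.metric], _content_key(y)))
    boot = bootstrap_delta_sd(sub, y, grid, config.B_boot, boot_seed,
                              min_per_side=config.grid.min_per_side,
                              stratified=config.stratified_bootstrap)
    pattern = classify_pattern(fit, _relative_slope_tol(fit,
                                                        config.slope_tol_frac))
    a0, a1, a2, a3, a4 = fit.coef
    row = {
        "region_id": s.region_id, "region_name": s.region_name,
        "metric": s.metric, "delta_hat": fit.delta_hat,
        "a0": a0, "a1": a1, "a2": a2, "a3": a3, "a4": a4,
        "rss": fit.rss, "p_raw": float(p_raw), "p_familywise": np.nan,
        "delta_sd": boot.delta_sd, "pattern": pattern, "n_used": fit.n_used,
        "status": "ok",
    }
    return row, stat_obs, nulls


def _save_null_stats(out_dir, metric, null_matrix, region_ids) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(null_matrix, columns=[str(r) for r in region_ids]).to_csv(
        out / f"null_stats_{metric}.csv.gz", index=False)


def significant_regions(results: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Rows with familywise p below ``alpha``, earliest change-point first.

    ``alpha >= 1`` returns every fitted row (p-values never exceed 1, so
    the threshold is vacuous).
    """
    p = results["p_familywise"]
    keep = p.notna() if alpha >= 1.0 else (p < alpha)
    return (results[keep]
            .sort_values(["delta_hat", "region_id"])
            .reset_index(drop=True))


def export_fixed_delta_panel(cohort: CohortTable, fa_results: pd.DataFrame,
                             ad_rd_sets: list[RegionMetricSet],
                             regions: list[int]) -> pd.DataFrame:
    """Data behind a trajectory panel: AD/RD re-fitted at FA change-points.

    For each requested region, the AD and RD values are fitted with the
    change-point fixed at the region's FA-derived estimate; the export
    carries, per subject, the covariate-adjusted value and the
    GAB-dependent fitted trend, i.e. the dots and the black piecewise line
    of a trajectory figure, plus the segment slopes.
    """
    frames = []
    for rid in regions:
        fa = fa_results[(fa_results["region_id"] == rid)
                        & (fa_results["metric"] == "FA")]
        if len(fa) == 0 or not np.isfinite(fa["delta_hat"].iloc[0]):
            raise ValidationError(f"region {rid} has no FA change-point result")
        delta = float(fa["delta_hat"].iloc[0])
        for metric in ("AD", "RD"):
            match = [s for s in ad_rd_sets
                     if s.region_id == rid and s.metric == metric]
            if not match:
                raise ValidationError(
                    f"region {rid} has no {metric} data for the panel")
            s = match[0]
            sub, y = s.complete_case(cohort)
            fit = fit_fixed_delta(sub, y, delta)
            frames.append(pd.DataFrame({
                "region_id": rid, "region_name": s.region_name,
                "metric": metric, "delta_fa": delta,
                "subject_id": sub.subject_id, "gab": sub.gab,
                "group": sub.group,
                "value_adjusted": adjust_covariates(sub, y, fit),
                "trend": gab_trend_values(sub, fit),
                "pre_slope": fit.pre_slope, "post_slope": fit.post_slope,
            }))
    if not frames:
        return pd.DataFrame(columns=[
            "region_id", "region_name", "metric", "delta_fa", "subject_id",
            "gab", "group", "value_adjusted", "trend", "pre_slope",
            "post_slope"])
    return pd.concat(frames, ignore_index=True)
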