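"""Resampling inference for the change-point model.

Three procedures, all propagating the change-point *search* into the
resampling distribution:

* a Freedman–Lane permutation test of the hinge term (nuisance covariates
  — intercept, linear GAB, PMA, sex — are kept intact under the null by
  permuting reduced-model residuals);
* a case-resampling bootstrap for the standard deviation of the estimated
  change-point;
* familywise error control across regions via the max-statistic over
  permutations shared between regions (Bonferroni as fallback).

The permutation null re-profiles the change-point for every permuted
response. Because the candidate designs do not change when y is permuted,
the per-candidate QR factorisations are computed once and reused; tests
cross-check this against a from-scratch refit loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_io import CohortTable
from .core import (ChangePointFit, N_COEF, _argmin_tied_low, _design_tensor,
                   _filter_grid, fit_ls, profile_changepoint)
from .errors import ConfigurationError, NoFitError, UnstableBootstrapError

#: sentinel returned when the full model fits exactly (rss -> 0): keeps
#: comparisons against null statistics well-defined
STAT_CAP = 1e12


@dataclass
class PermutationResult:
    stat_obs: float
    null_stats: np.ndarray
    p_raw: float
    seed: int | None
    B: int


@dataclass
class BootstrapResult:
    delta_samples: np.ndarray
    delta_sd: float
    n_failed: int
    seed: int | None


@dataclass
class FamilywiseResult:
    p_raw_by_region: np.ndarray
    p_fwe_by_region: np.ndarray
    method: str


def _stat_from_rss(rss_red, rss_full, n: int, scale) -> np.ndarray:
    """F-like improvement statistic for the added hinge term.

    ((rss_red - rss_full) / 1) / (rss_full / (n - 5)); one extra regression
    df in the numerator (the df spent selecting the change-point is
    absorbed by re-searching inside the permutation null, not by an F
    reference distribution). Scale-free in y.
    """
    rss_red = np.asarray(rss_red, dtype=float)
    rss_full = np.asarray(rss_full, dtype=float)
    tiny = 1e-14 * np.asarray(scale, dtype=float) + 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (rss_red - rss_full) * (n - N_COEF) / rss_full
    stat = np.where(rss_full < tiny,
                    np.where(rss_red < tiny, 0.0, STAT_CAP), stat)
    return np.clip(stat, 0.0, STAT_CAP)


class ProfileEngine:
    """Shared per-candidate factorisations for profiling many responses.

    Built once per (cohort, grid); ``null_stats`` then evaluates the
    change-point statistic for a whole matrix of responses in a few
    batched products.
    """

    def __init__(self, cohort: CohortTable, grid: np.ndarray):
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ConfigurationError("empty change-point grid")
        X = _design_tensor(cohort, grid)
        Q, R = np.linalg.qr(X)
        diag = np.abs(np.diagonal(R, axis1=1, axis2=2))
        ok = diag.min(axis=1) > 1e-9 * diag.max(axis=1)
        if not ok.any():
            raise NoFitError("every candidate change-point is rank deficient")
        self.grid = grid[ok]
        self.QT = Q[ok].transpose(0, 2, 1)          # (D, 5, n)
        Xr = X[0][:, [0, 1, 3, 4]]                  # reduced: no hinge column
        self.Q_red, _ = np.linalg.qr(Xr)
        self.n = cohort.n

    def rss_profiles(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(rss_reduced (B,), rss_full (D, B)) for responses Y of shape (n, B)."""
        Y = Y - Y.mean(axis=0)      # intercept absorbs this; tames cancellation
        yty = np.einsum("nb,nb->b", Y, Y)
        qr = self.Q_red.T @ Y
        rss_red = np.maximum(yty - np.einsum("kb,kb->b", qr, qr), 0.0)
        qf = np.einsum("dkn,nb->dkb", self.QT, Y)
        rss_full = np.maximum(yty[None, :] - np.einsum("dkb,dkb->db", qf, qf),
                              0.0)
        return rss_red, rss_full

    def stats(self, Y: np.ndarray) -> np.ndarray:
        """Change-point statistic for each column of Y."""
        rss_red, rss_full = self.rss_profiles(Y)
        Yc = Y - Y.mean(axis=0)
        sstot = np.einsum("nb,nb->b", Yc, Yc)
        return _stat_from_rss(rss_red, rss_full.min(axis=0), self.n, sstot)


def changepoint_stat(cohort: CohortTable, y: np.ndarray,
                     grid: np.ndarray) -> tuple[float, ChangePointFit]:
    """Observed change-point statistic and the underlying profiled fit."""
    y = np.asarray(y, dtype=float)
    fit = profile_changepoint(cohort, y, grid)
    base = np.column_stack([np.ones(cohort.n), cohort.gab, cohort.pma,
                            cohort.sex.astype(float)])
    reduced = fit_ls(base, y)
    sstot = float(((y - y.mean()) ** 2).sum())
    stat = _stat_from_rss(reduced.rss, fit.rss, cohort.n, sstot)
    return float(stat), fit


def draw_permutations(n: int, B: int, seed) -> np.ndarray:
    """B independent permutations of range(n), shape (B, n)."""
    rng = np.random.default_rng(seed)
    return rng.permuted(np.broadcast_to(np.arange(n), (B, n)), axis=1)


def permutation_null_stats(cohort: CohortTable, y: np.ndarray,
                           grid: np.ndarray, perms: np.ndarray,
                           engine: "ProfileEngine | None" = None
                           ) -> tuple[float, np.ndarray]:
    """Freedman–Lane null statistics for given subject shuffles.

    The reduced (no-hinge) model is fitted once; each permutation shuffles
    its residuals, adds back the reduced fitted values, and re-runs the
    full profile search on the reconstructed response. A prebuilt
    ``ProfileEngine`` for the same (cohort, grid) may be passed to share
    factorisations across regions.
    """
    y = np.asarray(y, dtype=float)
    base = np.column_stack([np.ones(cohort.n), cohort.gab, cohort.pma,
                            cohort.sex.astype(float)])
    reduced = fit_ls(base, y)
    fitted = base @ reduced.coef
    resid = y - fitted
    Y = fitted[:, None] + resid[perms.T]            # (n, B)
    if engine is None:
        engine = ProfileEngine(cohort, grid)
    stat_obs, _ = changepoint_stat(cohort, y, grid)
    return stat_obs, engine.stats(Y)


def permutation_test(cohort: CohortTable, y: np.ndarray, grid: np.ndarray,
                     B: int, seed, perms: np.ndarray | None = None
                     ) -> PermutationResult:
    """Permutation p-value for the presence of a change-point.

    ``p_raw = (1 + #{null >= observed}) / (B + 1)``; deterministic given
    ``seed``. Pre-drawn ``perms`` (shape (B, n)) may be supplied so many
    regions share the same shuffles for max-statistic correction.
    """
    if B < 1:
        raise ConfigurationError("need at least one permutation")
    if perms is None:
        perms = draw_permutations(cohort.n, B, seed)
    elif perms.shape != (B, cohort.n):
        raise ValueError(f"perms must have shape ({B}, {cohort.n})")
    stat_obs, null_stats = permutation_null_stats(cohort, y, grid, perms)
    p_raw = (1.0 + np.count_nonzero(null_stats >= stat_obs)) / (B + 1.0)
    return PermutationResult(stat_obs, null_stats, float(p_raw),
                             seed if np.isscalar(seed) else None, B)


def bootstrap_delta_sd(cohort: CohortTable, y: np.ndarray, grid: np.ndarray,
                       B_boot: int, seed, min_per_side: int = 5,
                       stratified: bool = False) -> BootstrapResult:
    """Case-resampling bootstrap SD of the estimated change-point.

    Subjects are drawn with replacement (n constant; optionally within
    preterm/term strata) and the full profile search re-run per resample,
    so the grid-selection step is inside the bootstrap. Resamples whose
    resampled GAB distribution leaves no identifiable candidate are
    counted in ``n_failed`` and excluded; more than 50% failures raises.
    """
    if B_boot < 2:
        raise ConfigurationError("need at least two bootstrap resamples")
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    n = cohort.n
    strata = ([np.flatnonzero(cohort.group == g) for g in ("preterm", "term")]
              if stratified else [np.arange(n)])
    deltas, n_failed = [], 0
    for _ in range(B_boot):
        idx = np.concatenate([s[rng.integers(0, s.size, s.size)]
                              for s in strata])
        sub = cohort.resample(idx)
        valid = _filter_grid(grid, sub.gab, min_per_side)
        if valid.size == 0:
            n_failed += 1
            continue
        try:
            engine = ProfileEngine(sub, valid)
        except NoFitError:
            n_failed += 1
            continue
        yb = y[idx]
        _, rss_full = engine.rss_profiles(yb[:, None])
        rss = rss_full[:, 0]
        ybc = yb - yb.mean()
        deltas.append(engine.grid[_argmin_tied_low(rss, float(ybc @ ybc))])
    if n_failed > 0.5 * B_boot:
        raise UnstableBootstrapError(
            f"{n_failed}/{B_boot} bootstrap resamples had no identifiable "
            "change-point candidate")
    samples = np.asarray(deltas, dtype=float)
    sd = float(samples.std(ddof=1)) if samples.size > 1 else float("nan")
    return BootstrapResult(samples, sd, n_failed,
                           seed if np.isscalar(seed) else None)


def familywise_adjust(stat_obs: np.ndarray, null_stats_matrix: np.ndarray,
                      method: str = "maxstat") -> FamilywiseResult:
    """Familywise-adjusted permutation p-values across R regions.

    ``maxstat`` compares each region's observed statistic with the
    permutation distribution of the across-region maximum; it requires the
    same B subject shuffles behind every column of ``null_stats_matrix``
    (B x R). ``bonferroni`` multiplies raw p-values by R.
    """
    stat_obs = np.asarray(stat_obs, dtype=float)
    null_stats_matrix = np.asarray(null_stats_matrix, dtype=float)
    R = stat_obs.size
    if null_stats_matrix.ndim != 2 or null_stats_matrix.shape[1] != R:
        raise ValueError(
            f"null matrix has {null_stats_matrix.shape} columns for {R} regions")
    B = null_stats_matrix.shape[0]
    p_raw = (1.0 + (null_stats_matrix >= stat_obs[None, :]).sum(axis=0)) / (B + 1.0)
    if method == "maxstat":
        max_null = null_stats_matrix.max(axis=1)
        p_fwe = (1.0 + (max_null[:, None] >= stat_obs[None, :]).sum(axis=0)) / (B + 1.0)
    elif method == "bonferroni":
        p_fwe = np.minimum(1.0, R * p_raw)
    else:
        raise ConfigurationError(f"unknown familywise method '{method}'")
    return FamilywiseResult(p_raw, p_fwe, method)
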