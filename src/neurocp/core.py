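"""Piecewise-linear (broken-stick) change-point regression.

The model for one region's metric is

    y_k = a0 + a1*g_k + a2*(g_k - D)*H(g_k - D) + a3*p_k + a4*s_k + e_k

with g the gestational age at birth (weeks), p the postmenstrual age at
scan, s the binary sex code, and H the *strict* indicator H(x) = 1 iff
x > 0. a1 is the pre-change slope, a1 + a2 the post-change slope, and the
change-point D is estimated by profiling the residual sum of squares over
a candidate grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .cohort_io import CohortTable
from .errors import (ConfigurationError, InsufficientDataError, NoFitError,
                     RankDeficiencyError)

N_COEF = 5

#: relative threshold on QR diagonal below which a candidate design is
#: treated as rank deficient (hinge column collinear with the others)
_RANK_RTOL = 1e-9

#: relative tolerance used to declare RSS values tied in the profile search
_TIE_RTOL = 1e-8


@dataclass(frozen=True)
class DeltaGridSpec:
    """Candidate change-point grid: lo..hi (weeks) in steps of `step`.

    Candidates keeping fewer than ``min_per_side`` subjects strictly on
    either side are discarded — they are unidentifiable or wildly
    leverage-dominated. Defaults span the preterm GAB range at the 0.1-week
    resolution the reported change-points carry.
    """

    lo: float = 24.0
    hi: float = 36.5
    step: float = 0.1
    min_per_side: int = 5

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigurationError("delta grid requires lo < hi")
        if self.step <= 0:
            raise ConfigurationError("delta grid step must be positive")
        if self.min_per_side < 2:
            raise ConfigurationError("min_per_side must be at least 2")


@dataclass
class ChangePointFit:
    """Result of a (profiled or fixed-D) change-point fit.

    ``coef`` is ``[a0, a1, a2, a3, a4]``; the post-change slope is the
    derived quantity ``a1 + a2``. ``rss_profile`` is aligned to
    ``delta_grid`` and ``rss == rss_profile.min()``.
    """

    delta_hat: float
    coef: np.ndarray
    rss: float
    n_used: int
    delta_grid: np.ndarray
    rss_profile: np.ndarray

    @property
    def pre_slope(self) -> float:
        return float(self.coef[1])

    @property
    def post_slope(self) -> float:
        return float(self.coef[1] + self.coef[2])


class LSFit(NamedTuple):
    coef: np.ndarray
    rss: float
    rank_deficient: bool


def hinge(g, delta):
    """(g - delta) * H(g - delta) with the strict indicator H(x)=1 iff x>0.

    Vectorised over ``g``; returns 0 exactly at g == delta.
    """
    g = np.asarray(g, dtype=float)
    out = np.where(g > delta, g - delta, 0.0)
    return out if out.ndim else float(out)


def build_design(cohort: CohortTable, delta: float) -> np.ndarray:
    """n x 5 design matrix with columns [1, g, hinge(g, delta), p, s]."""
    n = cohort.n
    if n < N_COEF:
        raise InsufficientDataError(
            f"need at least {N_COEF} subjects, got {n}")
    return np.column_stack([
        np.ones(n), cohort.gab, hinge(cohort.gab, delta), cohort.pma,
        cohort.sex.astype(float),
    ])


def fit_ls(X: np.ndarray, y: np.ndarray) -> LSFit:
    """Ordinary least squares for ||y - X c||^2.

    Rank-deficient systems return the minimum-norm solution with
    ``rank_deficient=True``; callers must treat such fits as invalid
    change-point candidates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError(
            f"dimension mismatch: X is {X.shape}, y has length {y.shape}")
    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(
            f"need more observations ({n}) than coefficients ({k})")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return LSFit(coef, float(resid @ resid), rank < k)


def make_delta_grid(cohort: CohortTable, spec: DeltaGridSpec) -> np.ndarray:
    """Arithmetic grid lo, lo+step, ... <= hi, filtered for identifiability."""
    n_steps = int(np.floor((spec.hi - spec.lo) / spec.step + 1e-9))
    grid = spec.lo + spec.step * np.arange(n_steps + 1)
    grid = _filter_grid(grid, cohort.gab, spec.min_per_side)
    if grid.size == 0:
        raise ConfigurationError(
            "no candidate change-point keeps "
            f"{spec.min_per_side} subjects strictly on each side")
    return grid


def _filter_grid(grid: np.ndarray, g: np.ndarray, min_per_side: int) -> np.ndarray:
    below = (g[:, None] < grid[None, :]).sum(axis=0)
    above = (g[:, None] > grid[None, :]).sum(axis=0)
    return grid[(below >= min_per_side) & (above >= min_per_side)]


def _design_tensor(cohort: CohortTable, grid: np.ndarray) -> np.ndarray:
    """Stack of design matrices, shape (len(grid), n, 5)."""
    base = build_design(cohort, grid[0])
    X = np.broadcast_to(base, (grid.size,) + base.shape).copy()
    X[:, :, 2] = hinge(cohort.gab[None, :], grid[:, None])
    return X


def profile_rss(cohort: CohortTable, y: np.ndarray,
                grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RSS of the full model at every grid candidate.

    Returns ``(rss, ok)`` aligned to ``grid``; ``ok`` is False (and rss
    +inf) where the design is rank deficient. Uses one batched QR, so the
    cost is one factorisation per candidate regardless of how many y
    vectors are later profiled against the same factorisation.
    """
    X = _design_tensor(cohort, grid)
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diagonal(R, axis1=1, axis2=2))
    ok = diag.min(axis=1) > _RANK_RTOL * diag.max(axis=1)
    # centring y changes only the fitted intercept, and keeps the
    # cancellation error of ||y||^2 - ||Q'y||^2 on the residual scale
    yc = y - y.mean()
    qty = np.einsum("dnk,n->dk", Q, yc)
    rss = np.maximum(yc @ yc - np.einsum("dk,dk->d", qty, qty), 0.0)
    rss = np.where(ok, rss, np.inf)
    return rss, ok


def _argmin_tied_low(rss: np.ndarray, scale: float) -> int:
    """Index of the minimal RSS; near-ties resolved to the smallest delta.

    ``scale`` (sum of squares of centred y) sets an absolute floor
    absorbing the cancellation
    noise of the QR-based RSS, so numerically-constant profiles (e.g. a
    truly linear trajectory) resolve deterministically to the first
    candidate.
    """
    best = rss.min()
    tol = _TIE_RTOL * best + 1e-12 * scale
    return int(np.flatnonzero(rss <= best + tol)[0])


def profile_changepoint(cohort: CohortTable, y: np.ndarray,
                        grid: np.ndarray) -> ChangePointFit:
    """Profile the change-point over ``grid`` and fit at the best candidate.

    delta_hat minimises the RSS; exact or floating-point ties are broken
    toward the smallest delta, and rank-deficient candidates are excluded
    from the profile.
    """
    grid = np.asarray(grid, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid.size == 0:
        raise ConfigurationError("empty change-point grid")
    if np.isnan(y).any():
        raise ValueError("y contains missing values; apply complete_case first")
    rss, ok = profile_rss(cohort, y, grid)
    if not ok.any():
        raise NoFitError("every candidate change-point is rank deficient")
    grid, rss = grid[ok], rss[ok]
    yc = y - y.mean()
    idx = _argmin_tied_low(rss, float(yc @ yc))
    delta_hat = float(grid[idx])
    refit = fit_ls(build_design(cohort, delta_hat), y)
    rss = rss.copy()
    rss[idx] = refit.rss
    return ChangePointFit(delta_hat, refit.coef, refit.rss, cohort.n, grid, rss)


def fit_fixed_delta(cohort: CohortTable, y: np.ndarray,
                    delta: float) -> ChangePointFit:
    """Fit the model at an externally supplied change-point.

    Used to re-fit AD/RD at an FA-derived change-point. Raises
    RankDeficiencyError when ``delta`` leaves the hinge column collinear
    with the rest of the design.
    """
    y = np.asarray(y, dtype=float)
    res = fit_ls(build_design(cohort, delta), y)
    if res.rank_deficient:
        raise RankDeficiencyError(
            f"design is rank deficient at delta = {delta}")
    return ChangePointFit(float(delta), res.coef, res.rss, cohort.n,
                          np.array([float(delta)]), np.array([res.rss]))


def adjust_covariates(cohort: CohortTable, y: np.ndarray,
                      fit: ChangePointFit) -> np.ndarray:
    """Remove the fitted PMA and sex contributions, centred at cohort means.

    Returns ``y - a3*(p - mean(p)) - a4*(s - mean(s))``: the values behind
    scatter plots of metric against GAB "after correcting for PMA at scan
    and sex". Centring keeps the mean (and scale) of y unchanged.
    """
    a3, a4 = fit.coef[3], fit.coef[4]
    p = cohort.pma - cohort.pma.mean()
    s = cohort.sex.astype(float) - cohort.sex.mean()
    return np.asarray(y, dtype=float) - a3 * p - a4 * s


def gab_trend_values(cohort: CohortTable, fit: ChangePointFit) -> np.ndarray:
    """GAB-dependent fitted trend a0 + a1*g + a2*hinge(g, delta) per subject.

    The piecewise-linear "black line" of the trajectory plots; continuous
    at the change-point by construction of the hinge.
    """
    a0, a1, a2 = fit.coef[0], fit.coef[1], fit.coef[2]
    return a0 + a1 * cohort.gab + a2 * hinge(cohort.gab, fit.delta_hat)
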