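"""Independent reference implementations used only to cross-check neurocp.

Everything here refits from scratch with plain numpy calls and never
shares code with the package's fitting paths.
"""

import numpy as np


def normal_equations(X, y):
    """OLS via explicit normal equations (X'X)^-1 X'y."""
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def brute_design(g, p, s, delta):
    h = np.where(g > delta, g - delta, 0.0)
    return np.column_stack([np.ones(g.size), g, h, p, s])


def brute_profile(g, p, s, y, grid, tie_rtol=1e-8):
    """From-scratch profile search: refit at every candidate with lstsq.

    Returns (delta_hat, rss_by_delta, kept_grid). Rank-deficient
    candidates are dropped; RSS values within a small tolerance of the
    minimum are tied and resolved to the smallest delta.
    """
    kept, rss = [], []
    for d in grid:
        X = brute_design(g, p, s, d)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            continue
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        kept.append(d)
        rss.append(float(r @ r))
    kept = np.asarray(kept)
    rss = np.asarray(rss)
    yc = y - y.mean()
    tol = tie_rtol * rss.min() + 1e-12 * float(yc @ yc)
    delta_hat = kept[rss <= rss.min() + tol][0]
    return float(delta_hat), rss, kept


def brute_stat(g, p, s, y, grid):
    """Change-point statistic recomputed from scratch."""
    n = g.size
    Xr = np.column_stack([np.ones(n), g, p, s])
    cr, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
    rr = y - Xr @ cr
    rss_red = float(rr @ rr)
    _, rss, _ = brute_profile(g, p, s, y, grid)
    rss_full = float(rss.min())
    sstot = float(((y - y.mean()) ** 2).sum())
    if rss_full < 1e-14 * sstot + 1e-300:
        return 0.0 if rss_red < 1e-14 * sstot + 1e-300 else 1e12
    return min((rss_red - rss_full) * (n - 5) / rss_full, 1e12)


def brute_maxstat_pfwe(stat_obs, null_matrix):
    """Familywise p by explicitly materialising the max-statistic law."""
    max_dist = np.array([row.max() for row in null_matrix])
    B = len(max_dist)
    return np.array([(1 + int((max_dist >= s).sum())) / (B + 1)
                     for s in stat_obs])
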