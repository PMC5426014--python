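import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurocp import (DeltaGridSpec, adjust_covariates, build_design,
                     fit_fixed_delta, fit_ls, gab_trend_values, hinge,
                     make_delta_grid, profile_changepoint)
from neurocp.errors import (ConfigurationError, InsufficientDataError,
                            RankDeficiencyError)
from conftest import region_values
from oracles import brute_profile, normal_equations


class TestHinge:
    @pytest.mark.parametrize("g,delta,expected", [
        (32.0, 30.0, 2.0),
        (30.0, 30.0, 0.0),   # strict inequality: H = 0 exactly at the knot
        (23.7, 30.0, 0.0),
    ])
    def test_definition(self, g, delta, expected):
        assert hinge(g, delta) == expected

    @given(g=st.floats(20, 45), delta=st.floats(20, 45))
    @settings(max_examples=50, derandomize=True)
    def test_nonnegative_and_continuous(self, g, delta):
        v = hinge(g, delta)
        assert v >= 0
        assert v == (g - delta if g > delta else 0.0)


class TestDesign:
    def test_row_layout(self):
        from neurocp import CohortTable
        c = CohortTable([f"s{i}" for i in range(5)],
                        [40, 25, 31, 39, 28], [43, 42, 44, 43, 43],
                        [1, 0, 1, 0, 1], ["term", "preterm", "preterm",
                                          "term", "preterm"])
        X = build_design(c, 30.0)
        np.testing.assert_array_equal(X[0], [1, 40, 10, 43, 1])
        np.testing.assert_array_equal(X[:, 2],
                                      np.where(c.gab > 30, c.gab - 30, 0))

    def test_all_below_delta_gives_zero_hinge(self, cohort):
        X = build_design(cohort, 50.0)
        assert (X[:, 2] == 0).all()

    def test_delta_below_min_gab_is_shifted_g(self, cohort):
        X = build_design(cohort, 10.0)
        np.testing.assert_allclose(X[:, 2], cohort.gab - 10.0)

    def test_too_few_subjects(self, cohort):
        small = cohort.subset(np.arange(4))
        with pytest.raises(InsufficientDataError):
            build_design(small, 30.0)


class TestFitLS:
    def test_exact_interpolation(self):
        g = np.linspace(24, 42, 10)
        X = np.column_stack([np.ones(10), g])
        res = fit_ls(X, 1.0 + 2.0 * g)
        np.testing.assert_allclose(res.coef, [1.0, 2.0], atol=1e-10)
        assert res.rss < 1e-20
        assert not res.rank_deficient

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        res = fit_ls(X, y)
        coef, rss = normal_equations(X, y)
        np.testing.assert_allclose(res.coef, coef, rtol=1e-8)
        np.testing.assert_allclose(res.rss, rss, rtol=1e-8)

    def test_duplicated_column_flags_rank_deficiency(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        X = np.column_stack([X, X[:, 1]])
        assert fit_ls(X, rng.normal(size=20)).rank_deficient

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            fit_ls(np.ones((10, 2)), np.ones(9))

    def test_underdetermined(self):
        with pytest.raises(InsufficientDataError):
            fit_ls(np.ones((4, 5)), np.ones(4))


class TestDeltaGrid:
    def test_grid_keeps_min_per_side(self, cohort):
        spec = DeltaGridSpec(lo=25, hi=36, step=0.5, min_per_side=5)
        grid = make_delta_grid(cohort, spec)
        assert grid.min() >= 25 and grid.max() <= 36
        for d in grid:
            assert (cohort.gab < d).sum() >= 5
            assert (cohort.gab > d).sum() >= 5

    def test_infeasible_min_per_side(self, cohort):
        with pytest.raises(ConfigurationError):
            make_delta_grid(cohort, DeltaGridSpec(min_per_side=50))

    def test_step_arithmetic(self, cohort):
        grid = make_delta_grid(cohort, DeltaGridSpec(lo=25, hi=36, step=11,
                                                     min_per_side=2))
        # {25, 36} before filtering; both sides populated for each survivor
        assert set(grid) <= {25.0, 36.0}

    def test_bad_spec(self):
        with pytest.raises(ConfigurationError):
            DeltaGridSpec(lo=30, hi=25)
        with pytest.raises(ConfigurationError):
            DeltaGridSpec(step=-1)


class TestProfile:
    def test_noiseless_recovery(self, cohort, grid):
        y = region_values(cohort, "rise_plateau", delta=30.0, noise_sd=0.0)
        fit = profile_changepoint(cohort, y, grid)
        assert fit.delta_hat == 30.0
        assert fit.rss <= 1e-16
        assert fit.rss == fit.rss_profile.min()

    def test_linear_data_tie_breaks_to_smallest_delta(self, cohort, grid):
        y = 0.1 + 0.005 * cohort.gab + 0.002 * cohort.pma
        fit = profile_changepoint(cohort, y, grid)
        assert fit.delta_hat == grid[0]
        assert np.allclose(fit.rss_profile, fit.rss_profile[0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, cohort, grid, seed):
        y = region_values(cohort, "plateau_decline", delta=31.0,
                          noise_sd=0.01, seed=seed)
        fit = profile_changepoint(cohort, y, grid)
        d_oracle, rss_oracle, kept = brute_profile(
            cohort.gab, cohort.pma, cohort.sex, y, grid)
        assert fit.delta_hat == d_oracle
        np.testing.assert_allclose(fit.rss_profile, rss_oracle,
                                   rtol=1e-7, atol=1e-12)

    def test_nesting_beats_reduced_model(self, cohort, grid):
        """The best hinge model never fits worse than the no-hinge model."""
        rng = np.random.default_rng(11)
        y = rng.normal(0.3, 0.05, cohort.n)
        fit = profile_changepoint(cohort, y, grid)
        Xr = np.column_stack([np.ones(cohort.n), cohort.gab, cohort.pma,
                              cohort.sex])
        _, rss_red = normal_equations(Xr, y)
        assert fit.rss <= rss_red + 1e-12

    def test_profile_invariant_to_constant_shift(self, cohort, grid):
        y = region_values(cohort, noise_sd=0.01, seed=3)
        f1 = profile_changepoint(cohort, y, grid)
        f2 = profile_changepoint(cohort, y + 100.0, grid)
        assert f1.delta_hat == f2.delta_hat
        np.testing.assert_allclose(f1.rss_profile, f2.rss_profile,
                                   rtol=1e-6, atol=1e-8)


class TestFixedDelta:
    def test_consistent_with_profile(self, cohort, grid, noisy_region):
        fit = profile_changepoint(cohort, noisy_region.values, grid)
        fixed = fit_fixed_delta(cohort, noisy_region.values, fit.delta_hat)
        np.testing.assert_array_equal(fixed.coef, fit.coef)
        assert fixed.rss == fit.rss
        assert fixed.delta_grid.shape == (1,)

    def test_delta_outside_gab_range_is_rank_deficient(self, cohort):
        y = region_values(cohort, noise_sd=0.01)
        with pytest.raises(RankDeficiencyError):
            fit_fixed_delta(cohort, y, 10.0)

    def test_recovers_planted_post_slope(self, cohort):
        """AD-style data refit at an externally supplied change-point."""
        from neurocp import SimRegionSpec, simulate_region
        spec = SimRegionSpec(region_id=1, metric="AD", pattern="rise_plateau",
                             delta_true=31.0, a0=6.0, pre_slope=-0.05,
                             post_slope=-0.01, pma_slope=-0.01,
                             sex_effect=0.02, noise_sd=0.01)
        y = simulate_region(cohort, spec, seed=9).values
        fit = fit_fixed_delta(cohort, y, 31.0)
        assert abs(fit.pre_slope - (-0.05)) < 0.01
        assert abs(fit.post_slope - (-0.01)) < 0.01


class TestAdjustAndTrend:
    def test_zero_covariate_effects_identity(self, cohort, grid, noisy_region):
        fit = profile_changepoint(cohort, noisy_region.values, grid)
        fit.coef = fit.coef.copy()
        fit.coef[3] = fit.coef[4] = 0.0
        adj = adjust_covariates(cohort, noisy_region.values, fit)
        np.testing.assert_array_equal(adj, noisy_region.values)

    def test_removes_pma_effect(self, cohort, grid):
        y = 5.0 * cohort.pma + 0.001 * np.random.default_rng(0).normal(
            size=cohort.n)
        fit = profile_changepoint(cohort, y, grid)
        adj = adjust_covariates(cohort, y, fit)
        slope = np.polyfit(cohort.pma, adj, 1)[0]
        assert abs(slope) < 0.01  # residual PMA slope ~ 0 of original 5

    def test_mean_preserved(self, cohort, grid, noisy_region):
        fit = profile_changepoint(cohort, noisy_region.values, grid)
        adj = adjust_covariates(cohort, noisy_region.values, fit)
        assert abs(adj.mean() - noisy_region.values.mean()) < 1e-10

    def test_trend_is_continuous_and_piecewise(self, cohort, grid,
                                               noisy_region):
        fit = profile_changepoint(cohort, noisy_region.values, grid)
        a0, a1, a2 = fit.coef[:3]
        d = fit.delta_hat
        eps = 1e-9
        from neurocp import CohortTable
        lo = a0 + a1 * (d - eps)
        hi = a0 + a1 * (d + eps) + a2 * eps
        assert abs(hi - lo) < 1e-6
        trend = gab_trend_values(cohort, fit)
        pre = cohort.gab < d
        if pre.sum() > 1:
            sl = np.polyfit(cohort.gab[pre], trend[pre], 1)[0]
            np.testing.assert_allclose(sl, a1, atol=1e-8)
        post = cohort.gab > d
        sl = np.polyfit(cohort.gab[post], trend[post], 1)[0]
        np.testing.assert_allclose(sl, a1 + a2, atol=1e-8)
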