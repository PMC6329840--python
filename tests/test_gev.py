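"""Extreme-value analysis: L-moments, GEV fits, return levels, CIs, AD test."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from heatrisk import gev
from heatrisk.gev import (
    DegenerateFitError,
    GEVParams,
    ad_test_gev,
    block_maxima,
    confidence_interval,
    exceedance_probability,
    fit_gev_lmoments,
    fit_gev_mle,
    gev_cdf,
    gev_rvs,
    hazard_under_state,
    return_level,
    sample_lmoments,
)

from _oracles import lmoments_combinatorial


class TestBlockMaxima:
    def test_thirty_years_three_blocks(self):
        out = block_maxima(np.arange(30.0))
        assert out.shape == (3,)

    def test_values_match_direct_max(self):
        annual = np.concatenate([np.arange(1.0, 11.0), np.arange(21.0, 31.0), np.ones(10)])
        out = block_maxima(annual)
        assert list(out) == [10.0, 30.0, 1.0]

    def test_constant_series(self):
        assert np.all(block_maxima(np.full(40, 3.5)) == 3.5)

    def test_partial_blocks_rejected(self):
        with pytest.raises(ValueError):
            block_maxima(np.arange(25.0))

    def test_grid_axis_preserved(self, rng):
        annual = rng.normal(size=(30, 2, 2))
        out = block_maxima(annual)
        assert out.shape == (3, 2, 2)
        assert np.array_equal(out[0], annual[:10].max(axis=0))


class TestLMoments:
    def test_matches_combinatorial_oracle(self, rng):
        x = rng.gumbel(10, 2, size=50)
        l1, l2, t3 = sample_lmoments(x)
        o1, o2, o3 = lmoments_combinatorial(x)
        assert l1 == pytest.approx(o1, abs=1e-9)
        assert l2 == pytest.approx(o2, abs=1e-9)
        assert t3 == pytest.approx(o3, abs=1e-9)

    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(2024)
        x = rng.gumbel(10, 2, size=1000)
        fit = fit_gev_lmoments(x)
        assert abs(fit.loc - 10) < 0.2
        assert abs(fit.scale - 2) < 0.2
        assert 0 <= fit.shape < 0.05

    def test_weibull_branch_sample_floored_to_gumbel(self):
        # uniform data has tau3 = 0 < Gumbel's 0.1699: the unconstrained
        # shape estimate is negative, so the constrained fit is exactly Gumbel
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, size=200)
        fit = fit_gev_lmoments(x)
        assert fit.shape == 0.0
        l1, l2, _ = sample_lmoments(x)
        assert fit.scale == pytest.approx(l2 / np.log(2))
        assert fit.loc == pytest.approx(l1 - gev.EULER_GAMMA * fit.scale)

    def test_frechet_parameter_recovery(self):
        rng = np.random.default_rng(7)
        true = GEVParams(loc=5.0, scale=1.5, shape=0.2)
        x = np.asarray(gev_rvs(true, size=4000, rng=rng))
        fit = fit_gev_lmoments(x)
        assert fit.loc == pytest.approx(5.0, abs=0.15)
        assert fit.scale == pytest.approx(1.5, abs=0.15)
        assert fit.shape == pytest.approx(0.2, abs=0.08)

    def test_degenerate_sample_raises(self):
        with pytest.raises(DegenerateFitError):
            fit_gev_lmoments(np.full(25, 4.0))

    @given(st.integers(0, 2**32 - 1))
    def test_shape_never_negative(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        assert fit_gev_lmoments(x).shape >= 0.0

    def test_batch_fit_matches_scalar_fit(self, rng):
        samples = rng.gumbel(3, 1, size=(5, 40))
        mu, sigma, xi = gev.fit_gev_lmoments_batch(samples)
        for i in range(5):
            f = fit_gev_lmoments(samples[i])
            assert mu[i] == pytest.approx(f.loc)
            assert sigma[i] == pytest.approx(f.scale)
            assert xi[i] == pytest.approx(f.shape)


class TestReturnLevels:
    def test_gumbel_closed_form(self):
        p = GEVParams(loc=0.0, scale=1.0, shape=0.0)
        assert return_level(p, 500) == pytest.approx(-np.log(-np.log(0.998)))

    def test_frechet_closed_form(self):
        p = GEVParams(loc=0.0, scale=1.0, shape=0.2)
        yp = -np.log(1 - 1 / 100)
        expected = (yp**-0.2 - 1) / 0.2
        assert return_level(p, 100) == pytest.approx(expected, rel=1e-12)

    def test_invalid_return_period(self):
        with pytest.raises(ValueError):
            return_level(GEVParams(0, 1, 0.1), 1.0)

    @given(
        st.floats(-50, 50),
        st.floats(0.01, 20),
        st.floats(0, 0.8),
        st.floats(1.01, 1e4),
    )
    def test_inverse_pair_identity(self, mu, sigma, xi, T):
        p = GEVParams(loc=mu, scale=sigma, shape=xi)
        level = return_level(p, T)
        assert exceedance_probability(p, level) == pytest.approx(1.0 / T, rel=1e-9)

    def test_cdf_matches_scipy_genextreme(self, rng):
        # scipy uses the opposite shape sign: c = -xi
        for xi in (0.0, 0.15, 0.5):
            z = rng.normal(10, 5, size=50)
            ours = gev_cdf(z, 10.0, 2.0, xi)
            theirs = stats.genextreme.cdf(z, -xi, loc=10.0, scale=2.0)
            assert np.allclose(ours, theirs, atol=1e-12)

    def test_exceedance_limits_and_monotonicity(self):
        p = GEVParams(loc=0.0, scale=1.0, shape=0.1)
        assert exceedance_probability(p, -1e9) == pytest.approx(1.0)
        levels = np.linspace(-5, 20, 100)
        probs = np.asarray(exceedance_probability(p, levels))
        assert np.all(np.diff(probs) <= 0)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_exceedance_against_monte_carlo(self):
        rng = np.random.default_rng(31)
        p = GEVParams(loc=2.0, scale=1.5, shape=0.1)
        draws = np.asarray(gev_rvs(p, size=10**6, rng=rng))
        level = return_level(p, 50)
        emp = (draws > level).mean()
        se = np.sqrt(0.02 * 0.98 / 10**6)
        assert abs(emp - 0.02) < 3 * se


class TestHazardUnderState:
    def test_identical_fits_give_reciprocal_T(self):
        p = GEVParams(loc=1.0, scale=2.0, shape=0.1)
        assert hazard_under_state(p, p, 500) == pytest.approx(0.002)

    def test_location_shift_raises_probability(self):
        p = GEVParams(loc=1.0, scale=2.0, shape=0.1)
        warm = GEVParams(loc=2.0, scale=2.0, shape=0.1)
        assert hazard_under_state(p, warm, 500) > 0.002

    def test_grid_composition_matches_cellwise(self, rng):
        mu0 = rng.normal(10, 1, size=(3, 3))
        mu1 = mu0 + 0.5
        sigma = np.full((3, 3), 2.0)
        xi = np.full((3, 3), 0.1)
        grid = hazard_under_state((mu0, sigma, xi), (mu1, sigma, xi), 200)
        for i in range(3):
            for j in range(3):
                a = GEVParams(mu0[i, j], 2.0, 0.1)
                b = GEVParams(mu1[i, j], 2.0, 0.1)
                assert grid[i, j] == pytest.approx(float(hazard_under_state(a, b, 200)))


class TestConfidenceInterval:
    def test_alpha_one_collapses_to_point_estimate(self, rng):
        x = rng.gumbel(10, 2, size=50)
        lo, hi = confidence_interval(x, T=500, alpha=1.0)
        assert lo == hi
        mle = fit_gev_mle(x)
        assert lo == pytest.approx(float(return_level(mle, 500)))

    def test_interval_brackets_point_estimate(self, rng):
        x = rng.gumbel(10, 2, size=100)
        lo, hi = confidence_interval(x, T=500, alpha=0.05)
        z = float(return_level(fit_gev_mle(x), 500))
        assert lo < z < hi

    def test_more_blocks_narrow_the_interval(self):
        rng = np.random.default_rng(17)
        x_small = rng.gumbel(10, 2, size=30)
        x_large = rng.gumbel(10, 2, size=300)
        lo_s, hi_s = confidence_interval(x_small, T=500, min_blocks=20)
        lo_l, hi_l = confidence_interval(x_large, T=500, min_blocks=20)
        assert (hi_s - lo_s) > (hi_l - lo_l)

    def test_coverage_near_nominal(self):
        # 200 Gumbel(10, 2) samples of n=100 blocks; the 95% profile interval
        # should cover the true 500-block return level ~95% of the time
        rng = np.random.default_rng(404)
        true_z = float(return_level(GEVParams(10.0, 2.0, 0.0), 500))
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.gumbel(10, 2, size=100)
            lo, hi = confidence_interval(x, T=500, alpha=0.05)
            if np.isfinite(lo) and np.isfinite(hi) and lo <= true_z <= hi:
                hits += 1
        assert 0.90 <= hits / n_rep <= 1.00


class TestAndersonDarling:
    def test_statistic_matches_definition(self, rng):
        x = np.sort(rng.gumbel(0, 1, size=40))
        u = gev_cdf(x, 0.0, 1.0, 0.0)
        i = np.arange(1, 41)
        expected = -40 - np.sum((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1]))) / 40
        got = gev.anderson_darling_statistic(x, 0.0, 1.0, 0.0)
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_power_against_uniform_data(self):
        # n=200 blocks of uniform data should be rejected with high probability
        rejections = 0
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            x = rng.uniform(0, 1, size=200)
            _, p = ad_test_gev(x, n_boot=200, rng=rng)
            rejections += p < 0.05
        assert rejections >= 8

    def test_duplicated_sample_lowers_pvalue_on_average(self):
        p_orig, p_dup = [], []
        for rep in range(40):
            rng = np.random.default_rng(2000 + rep)
            x = rng.gumbel(10, 2, size=50)
            _, p1 = ad_test_gev(x, n_boot=100, rng=np.random.default_rng(rep))
            _, p2 = ad_test_gev(
                np.repeat(x, 2), n_boot=100, rng=np.random.default_rng(rep)
            )
            p_orig.append(p1)
            p_dup.append(p2)
        assert np.mean(p_dup) < np.mean(p_orig)

    def test_degenerate_sample_gives_missing_pvalue(self):
        a2, p = ad_test_gev(np.full(30, 2.0), n_boot=50)
        assert np.isnan(a2) and np.isnan(p)
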