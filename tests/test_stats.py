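"""Distribution fitting, goodness-of-fit, permutation and regression tests."""

import numpy as np
import pytest
from scipy import stats as sps

from xenoscan.stats import (
    chisq_gof,
    chisq_vs_background,
    fit_geometric_ml,
    fit_intronization,
    fit_yule_simon_ml,
    perm_spearman,
    yule_simon_pmf,
)
from xenoscan.synthetic import sample_birth_death_sizes, sample_yule_simon


class TestYuleSimonPmf:
    @pytest.mark.parametrize(
        "k,alpha,expected",
        [(1, 1.0, 0.5), (2, 1.0, 1 / 6), (3, 1.0, 1 / 12), (1, 2.0, 2 / 3)],
    )
    def test_analytic_values(self, k, alpha, expected):
        assert yule_simon_pmf(k, alpha) == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_reference(self):
        ks = np.arange(1, 50)
        for alpha in (0.7, 1.0, 2.0):
            np.testing.assert_allclose(
                yule_simon_pmf(ks, alpha), sps.yulesimon.pmf(ks, alpha), rtol=1e-10
            )

    @pytest.mark.parametrize("alpha", [1.0, 2.0])
    def test_sums_to_one(self, alpha):
        ks = np.arange(1, 10**6, dtype=float)
        assert yule_simon_pmf(ks, alpha).sum() == pytest.approx(1.0, abs=1e-5)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            yule_simon_pmf(0, 1.0)
        with pytest.raises(ValueError):
            yule_simon_pmf(1, -1.0)


class TestGeometricML:
    def test_all_ones_clamps_with_warning(self):
        fit = fit_geometric_ml([1, 1, 1])
        assert fit.parameter == 1.0
        assert fit.warnings

    def test_parameter_recovery(self):
        x = sample_birth_death_sizes(10_000, 0.47, seed=12)
        fit = fit_geometric_ml(x)
        assert abs(fit.parameter - 0.47) < 0.02

    def test_truncated_recovery(self):
        rng = np.random.default_rng(13)
        x = rng.geometric(0.47, size=20_000)
        xt = x[(x >= 1) & (x <= 12)]
        fit = fit_geometric_ml(xt, support=(1, 12), truncated=True)
        assert abs(fit.parameter - 0.47) < 0.02

    def test_truncated_requires_window(self):
        with pytest.raises(ValueError):
            fit_geometric_ml([1, 2, 3], truncated=True)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            fit_geometric_ml([])


def test_yule_simon_ml_recovery():
    x = sample_yule_simon(10_000, 1.0, seed=3)
    fit = fit_yule_simon_ml(x)
    assert abs(fit.parameter - 1.0) < 0.05


class TestChisqGof:
    def test_perfect_fit_gives_zero_statistic(self):
        # sample engineered to match Geometric(0.5) expectations on 1..3
        x = [1] * 40 + [2] * 20 + [3] * 10
        fit = chisq_gof(x, "geometric", 0.5, support=(1, 3))
        assert fit.statistic == pytest.approx(0.0, abs=1e-9)
        assert fit.pvalue == pytest.approx(1.0)

    def test_background_mode_hand_computed(self):
        stat, df, p = chisq_vs_background([30, 70], [50, 50])
        assert stat == pytest.approx(16.0)
        assert df == 1

    def test_pooling_respects_min_expected(self):
        x = list(sample_yule_simon(300, 1.0, seed=4))
        fit = chisq_gof(x, "yule_simon", 1.0, support=(1, 12))
        assert all(e >= 5 for e in fit.binning.expected)
        assert sum(fit.binning.observed) == len([v for v in x if 1 <= v <= 12])

    def test_too_few_bins_is_error(self):
        with pytest.raises(ValueError, match="bins"):
            chisq_gof([1, 1, 1], "geometric", 0.5, support=(1, 2))

    def test_calibration_under_true_model(self):
        # p-values under the true model should be roughly uniform: the
        # rejection rate at 0.05 stays in a loose binomial band
        rng = np.random.default_rng(5)
        rej = 0
        reps = 400
        for _ in range(reps):
            x = sample_yule_simon(500, 1.0, rng)
            fit = chisq_gof(x, "yule_simon", 1.0, support=(1, 12))
            rej += fit.pvalue < 0.05
        assert 0.02 <= rej / reps <= 0.09


class TestPermSpearman:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        rho, p = perm_spearman(x, x, n_perm=999, seed=1)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        rho, _ = perm_spearman(x, x[::-1], n_perm=99, seed=1)
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            perm_spearman([1, 1, 1], [1, 2, 3])

    def test_matches_scipy_rho_with_ties(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=30).astype(float) + 0.3 * x
        rho, _ = perm_spearman(x, y, n_perm=99, seed=0)
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_size_calibration_under_null(self):
        rng = np.random.default_rng(9)
        rej = 0
        reps = 300
        for _ in range(reps):
            x = rng.uniform(size=44)
            y = rng.uniform(size=44)
            _, p = perm_spearman(x, y, n_perm=499, seed=int(rng.integers(2**31)))
            rej += p < 0.05
        assert 0.02 <= rej / reps <= 0.09


class TestIntronization:
    def test_noiseless_slope_recovered(self):
        x = np.linspace(0.1, 3.0, 50)
        fit = fit_intronization(0.6 * x, x)
        assert fit.slope == pytest.approx(0.6)

    def test_single_point_closed_form(self):
        fit = fit_intronization([3.0], [2.0])
        assert fit.slope == pytest.approx(1.5)

    def test_poisson_recovery(self):
        from xenoscan.synthetic import sample_intronization

        x, y = sample_intronization(800, 0.6, seed=21)
        fit = fit_intronization(y, x)
        assert abs(fit.slope - 0.6) < 0.1
        assert fit.pvalue < 0.001

    def test_matches_statsmodels_no_intercept(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        x = rng.exponential(1.0, 60)
        y = rng.poisson(0.6 * x).astype(float)
        fit = fit_intronization(y, x)
        ols = sm.OLS(y, x).fit()
        assert fit.slope == pytest.approx(ols.params[0], rel=1e-10)
        # statsmodels uses n-1 residual df for the no-intercept model too
        assert fit.pvalue == pytest.approx(ols.pvalues[0], rel=1e-8)

    def test_all_zero_distances_error(self):
        with pytest.raises(ValueError):
            fit_intronization([1.0, 2.0], [0.0, 0.0])


class TestHeavyTailContrast:
    def test_geometric_fit_rejected_on_yule_sample(self):
        # the study-scale contrast: a heavy-tailed size sample defeats the
        # best-fitting truncated geometric but not the Yule-Simon(1) law
        x = sample_yule_simon(2000, 1.0, seed=41)
        windowed = x[(x >= 1) & (x <= 12)]
        gfit = fit_geometric_ml(windowed, support=(1, 12), truncated=True)
        ggof = chisq_gof(windowed, "geometric", gfit.parameter,
                         support=(1, 12), ddof=1)
        ygof = chisq_gof(windowed, "yule_simon", 1.0, support=(1, 12))
        assert ggof.pvalue < 1e-3
        assert ygof.pvalue > 0.01
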