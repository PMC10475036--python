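"""t-tests, effect-size conventions, correlations, Fisher z, robust IRLS."""

import math

import numpy as np
import pytest
from scipy import stats

from sociallearn import inference_stats as infs


class TestEffectSizeConversions:
    # printed (t, n1, n2, d) report pairs reproduced by the package's
    # independent-samples convention d = t*sqrt(1/n1 + 1/n2)
    @pytest.mark.parametrize("t, n1, n2, d", [
        (2.15, 21, 23, 0.65),
        (1.54, 21, 23, 0.46),
    ])
    def test_welch_convention_exact_to_2dp(self, t, n1, n2, d):
        assert round(infs.cohen_d_from_welch_t(t, n1, n2), 2) == d

    # pairs the source toolchain likely computed from raw SDs: our
    # conversion lands within 0.015 of the printed value
    @pytest.mark.parametrize("t, n1, n2, d", [
        (2.52, 21, 23, 0.77),
        (2.40, 21, 23, 0.73),
    ])
    def test_welch_convention_near(self, t, n1, n2, d):
        assert infs.cohen_d_from_welch_t(t, n1, n2) == pytest.approx(d, abs=0.015)

    @pytest.mark.parametrize("t, n, d", [
        (3.91, 23, 0.82),
        (-1.52, 21, 0.33),
    ])
    def test_paired_convention_exact_to_2dp(self, t, n, d):
        assert round(infs.cohen_d_from_paired_t(t, n), 2) == d

    def test_paired_convention_near(self):
        assert infs.cohen_d_from_paired_t(-2.61, 21) == pytest.approx(0.58, abs=0.015)


class TestWelchT:
    def test_identical_samples_zero_statistic(self, rng):
        x = rng.normal(size=10)
        res = infs.welch_t(x, x.copy())
        assert res.t == 0.0 and res.d == 0.0

    def test_zero_variance_both_raises(self):
        with pytest.raises(infs.DegenerateInputError):
            infs.welch_t([1.0, 1.0, 1.0], [2.0, 2.0])

    def test_df_bounded_by_pooled(self, rng):
        for _ in range(20):
            x = rng.normal(0, rng.uniform(0.5, 3), rng.integers(5, 30))
            y = rng.normal(0, rng.uniform(0.5, 3), rng.integers(5, 30))
            res = infs.welch_t(x, y)
            assert res.df <= len(x) + len(y) - 2 + 1e-9

    def test_df_equals_pooled_for_equal_variance_and_size(self, rng):
        x = rng.normal(size=15)
        res = infs.welch_t(x, x + 0.7)  # identical spread, shifted mean
        assert res.df == pytest.approx(28.0)

    def test_sign_of_t_matches_mean_difference(self, rng):
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        res = infs.welch_t(x, y)
        assert np.sign(res.t) == np.sign(res.mean_diff)

    def test_null_calibration_and_p_uniformity(self):
        rng = np.random.default_rng(2024)
        pvals = np.empty(10_000)
        for i in range(10_000):
            pvals[i] = infs.welch_t(rng.normal(size=21), rng.normal(size=23)).p
        assert 0.045 <= np.mean(pvals < 0.05) <= 0.055
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPairedT:
    def test_constant_shift_is_degenerate(self):
        x = np.array([0.1, 0.5, 0.9])
        with pytest.raises(infs.DegenerateInputError):
            infs.paired_t(x + 0.3, x)

    def test_effect_size_recovery_simulation(self):
        rng = np.random.default_rng(99)
        ds = [infs.paired_t(rng.normal(0.5, 1, 30), np.zeros(30)).d
              for _ in range(5000)]
        assert np.mean(ds) == pytest.approx(0.5, abs=0.05)


class TestPartialCorrelation:
    def test_orthogonal_covariate_reduces_to_pearson(self, rng):
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        z = rng.normal(size=60)
        # orthogonalise z against x, y, and the intercept
        Q = np.column_stack([np.ones(60), x, y])
        z = z - Q @ np.linalg.lstsq(Q, z, rcond=None)[0]
        plain = infs.pearson(x, y).r
        partial = infs.partial_correlation(x, y, z).r
        assert partial == pytest.approx(plain, abs=1e-10)

    def test_covariate_equal_to_x_kills_correlation(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert infs.partial_correlation(x, y, x).r == pytest.approx(0.0, abs=1e-10)

    def test_matches_precision_matrix_identity(self, rng):
        cov = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
        data = rng.multivariate_normal(np.zeros(3), cov, size=50)
        x, y, z = data.T
        omega = np.linalg.inv(np.corrcoef(data.T))
        oracle = -omega[0, 1] / math.sqrt(omega[0, 0] * omega[1, 1])
        assert infs.partial_correlation(x, y, z).r == pytest.approx(oracle, abs=1e-8)

    def test_constant_input_raises(self):
        with pytest.raises(infs.DegenerateInputError):
            infs.partial_correlation(np.ones(10), np.arange(10.0), np.arange(10.0))


class TestSpearman:
    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        r0 = infs.spearman(x, y).r
        assert infs.spearman(np.exp(x), y).r == pytest.approx(r0)
        assert infs.spearman(x, y ** 3).r == pytest.approx(r0)


class TestFisherZ:
    def test_zero_and_odd_symmetry(self):
        assert infs.fisher_z(0.0) == 0.0
        assert infs.fisher_z(-0.3) == -infs.fisher_z(0.3)

    def test_closed_form_value(self):
        assert infs.fisher_z(0.5) == pytest.approx(0.5493, abs=5e-5)

    def test_domain_error_at_unity(self):
        with pytest.raises(ValueError):
            infs.fisher_z(1.0)


class TestRobustRegression:
    def test_clean_data_close_to_ols(self, rng):
        x = rng.normal(size=200)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.01, 200)
        fit = infs.robust_regression(x, y)
        X = np.column_stack([np.ones(200), x])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.coef, ols, atol=1e-3)

    def test_clean_data_weights_near_one(self, rng):
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(0, 1, 100)
        fit = infs.robust_regression(x, y)
        assert np.mean(fit.weights >= 0.99) > 0.7
        assert np.median(fit.weights) == pytest.approx(1.0)

    def test_outlier_resistance_vs_ols(self):
        # one gross outlier (10x residual SD) planted at the highest-leverage
        # point; the robust slope should beat OLS almost always
        rng = np.random.default_rng(77)
        wins = 0
        n_sims = 300
        for _ in range(n_sims):
            x = rng.normal(size=50)
            y = 2.0 * x + rng.normal(0, 1, 50)
            y[np.argmax(np.abs(x))] += 10.0 * np.sign(rng.normal())
            X = np.column_stack([np.ones(50), x])
            ols_slope = np.linalg.lstsq(X, y, rcond=None)[0][1]
            rob_slope = infs.robust_regression(x, y).coef[1]
            wins += abs(rob_slope - 2.0) < abs(ols_slope - 2.0)
        assert wins / n_sims >= 0.95

    def test_downweights_gross_outlier(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.5, 50)
        y[7] += 20.0
        fit = infs.robust_regression(x, y)
        assert fit.weights[7] < 0.2

    def test_bisquare_family_available(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(0, 0.5, 60)
        fit = infs.robust_regression(x, y, family="bisquare")
        assert fit.coef.shape == (2,)
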