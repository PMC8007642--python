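"""Univariable MR estimators against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from mrpath.estimators import (
    EstimatorError,
    cochran_q,
    egger,
    ivw,
    mode_based,
    ratio_estimates,
    robust,
    weighted_median,
)
from mrpath.summary_io import LDCorrelationMatrix

from conftest import make_harmonised


class TestRatioEstimates:
    def test_single_ratio(self):
        h = make_harmonised([0.5, 1.0, 1.0], [0.25, 0.5, 0.5], [0.1, 0.1, 0.1])
        r = ratio_estimates(h)
        assert r["ratio"].iloc[0] == pytest.approx(0.5)
        assert r["se"].iloc[0] == pytest.approx(0.2)

    def test_joint_sign_flip_invariance(self):
        h1 = make_harmonised([0.5, 0.2, 0.4], [0.25, 0.1, 0.2], [0.1] * 3)
        h2 = make_harmonised([-0.5, -0.2, -0.4], [-0.25, -0.1, -0.2], [0.1] * 3)
        np.testing.assert_allclose(
            ratio_estimates(h1)["ratio"], ratio_estimates(h2)["ratio"]
        )

    def test_elementwise_division_oracle(self):
        x = np.array([0.11, -0.23, 0.31])
        y = np.array([0.05, 0.02, -0.14])
        sy = np.array([0.01, 0.02, 0.03])
        h = make_harmonised(x, y, sy)
        r = ratio_estimates(h)
        np.testing.assert_allclose(r["ratio"], y / x, rtol=1e-14)
        np.testing.assert_allclose(r["se"], sy / np.abs(x), rtol=1e-14)

    def test_zero_exposure_beta_names_variant(self):
        h = make_harmonised([0.5, 0.0, 0.4], [0.25, 0.1, 0.2], [0.1] * 3)
        with pytest.raises(EstimatorError, match="rs2"):
            ratio_estimates(h)


def _wls_through_origin(x, y, w):
    """Independent closed-form oracle for the IVW normal equations."""
    beta = np.sum(w * x * y) / np.sum(w * x * x)
    se_fixed = np.sqrt(1.0 / np.sum(w * x * x))
    q = np.sum(w * (y - beta * x) ** 2)
    return beta, se_fixed, q


class TestIVW:
    def test_identical_ratios_give_ratio_and_zero_q(self):
        x = np.array([0.1, 0.2, 0.4])
        h = make_harmonised(x, 0.5 * x, [0.01, 0.03, 0.02])
        est = ivw(h)
        assert est.beta == pytest.approx(0.5, rel=1e-12)
        assert est.q_statistic == pytest.approx(0.0, abs=1e-18)

    def test_three_snp_toy_matches_normal_equations(self, toy_harmonised):
        est = ivw(toy_harmonised, "fixed")
        x = np.array([0.1, 0.2, 0.3])
        y = np.array([0.05, 0.12, 0.14])
        w = np.full(3, 1e4)
        beta, se, q = _wls_through_origin(x, y, w)
        assert est.beta == pytest.approx(beta, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)
        assert est.q_statistic == pytest.approx(q, abs=1e-8)
        assert est.q_df == 2

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0.2, 0.05, 8)
            y = rng.normal(0.1, 0.1, 8) * x / 0.2
            sy = rng.uniform(0.01, 0.05, 8)
            h = make_harmonised(x, y, sy)
            e_f = ivw(h, "fixed")
            e_r = ivw(h, "random")
            assert e_r.se >= e_f.se - 1e-15
            if e_f.q_statistic <= e_f.q_df:
                assert e_r.se == pytest.approx(e_f.se, rel=1e-12)

    def test_identity_ld_equals_no_ld(self):
        x = [0.1, 0.2, 0.3, 0.15]
        y = [0.05, 0.12, 0.14, 0.06]
        sy = [0.01, 0.02, 0.01, 0.03]
        h_plain = make_harmonised(x, y, sy)
        h_ld = make_harmonised(x, y, sy, ld=np.eye(4))
        for model in ("fixed", "random"):
            a = ivw(h_plain, model)
            b = ivw(h_ld, model)
            assert a.beta == pytest.approx(b.beta, abs=1e-12)
            assert a.se == pytest.approx(b.se, abs=1e-12)
            assert a.q_statistic == pytest.approx(b.q_statistic, abs=1e-10)

    def test_correlated_ld_matches_manual_gls(self):
        x = np.array([0.1, 0.2, 0.3])
        y = np.array([0.05, 0.12, 0.14])
        sy = np.array([0.01, 0.02, 0.015])
        r = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.2], [0.1, 0.2, 1.0]])
        h = make_harmonised(x, y, sy, ld=r)
        est = ivw(h, "fixed")
        sigma = np.outer(sy, sy) * r
        si = np.linalg.inv(sigma)
        beta_o = (x @ si @ y) / (x @ si @ x)
        se_o = np.sqrt(1.0 / (x @ si @ x))
        assert est.beta == pytest.approx(beta_o, rel=1e-12)
        assert est.se == pytest.approx(se_o, rel=1e-12)

    def test_scale_equivariance(self):
        x = np.array([0.1, 0.2, 0.3, 0.25])
        y = np.array([0.05, 0.12, 0.14, 0.11])
        sy = np.array([0.01, 0.02, 0.01, 0.02])
        c = 3.7
        e1 = ivw(make_harmonised(x, y, sy))
        e2 = ivw(make_harmonised(c * x, y, sy))
        assert e2.beta == pytest.approx(e1.beta / c, rel=1e-12)

    def test_single_variant_degenerates_to_wald_ratio(self):
        h = make_harmonised([0.5], [0.25], [0.1])
        with pytest.warns(UserWarning, match="Wald"):
            est = ivw(h)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_or_scale_is_exp_of_log_scale(self, toy_harmonised):
        est = ivw(toy_harmonised)
        o, lo, hi = est.or_scale
        assert o == pytest.approx(np.exp(est.beta), rel=1e-12)
        assert lo == pytest.approx(np.exp(est.ci_low), rel=1e-12)
        assert hi == pytest.approx(np.exp(est.ci_high), rel=1e-12)
        assert est.ci_low < est.ci_high


def _weighted_regression_with_intercept(x, y, w):
    """Two-parameter weighted normal equations, solved by hand (2x2 inverse)."""
    s_w = np.sum(w)
    s_x = np.sum(w * x)
    s_xx = np.sum(w * x * x)
    s_y = np.sum(w * y)
    s_xy = np.sum(w * x * y)
    det = s_w * s_xx - s_x**2
    a = (s_xx * s_y - s_x * s_xy) / det
    b = (s_w * s_xy - s_x * s_y) / det
    var_a = s_xx / det
    var_b = s_w / det
    return a, b, np.sqrt(var_a), np.sqrt(var_b)


class TestEgger:
    def test_exact_affine_data_recovered_to_machine_precision(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        a, b = 0.02, -0.6
        y = a + b * x
        h = make_harmonised(x, y, [0.01] * 4)
        est = egger(h)
        assert est.beta == pytest.approx(b, abs=1e-12)
        assert est.intercept == pytest.approx(a, abs=1e-14)
        assert est.q_statistic == pytest.approx(0.0, abs=1e-16)

    def test_four_snp_toy_matches_hand_normal_equations(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([0.03, 0.12, 0.14, 0.21])
        sy = np.array([0.01, 0.02, 0.015, 0.01])
        h = make_harmonised(x, y, sy)
        est = egger(h)
        a, b, se_a, se_b = _weighted_regression_with_intercept(x, y, 1 / sy**2)
        assert est.beta == pytest.approx(b, abs=1e-10)
        assert est.intercept == pytest.approx(a, abs=1e-10)
        # multiplicative random-effects scaling applied to both SEs
        q = np.sum((1 / sy**2) * (y - a - b * x) ** 2)
        scale = max(1.0, np.sqrt(q / 2))
        assert est.se == pytest.approx(se_b * scale, rel=1e-10)
        assert est.intercept_se == pytest.approx(se_a * scale, rel=1e-10)
        assert est.q_df == 2

    def test_rows_oriented_to_positive_exposure_betas(self):
        x = np.array([0.1, -0.2, 0.3, -0.4])
        b = -0.5
        y = b * x
        h = make_harmonised(x, y, [0.01] * 4)
        est = egger(h)
        assert est.beta == pytest.approx(b, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_needs_three_variants(self):
        h = make_harmonised([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(EstimatorError):
            egger(h)

    def test_collinear_exposure_betas_rejected(self):
        h = make_harmonised([0.2, 0.2, 0.2], [0.1, 0.12, 0.09], [0.01] * 3)
        with pytest.raises(EstimatorError, match="collinear"):
            egger(h)

    def test_null_intercept_test_size_near_nominal(self):
        # strong instruments, no pleiotropy: ~5% of intercepts significant
        rng = np.random.default_rng(2024)
        j, theta = 50, -0.3
        rejections = 0
        reps = 400
        for _ in range(reps):
            gamma = rng.uniform(0.03, 0.1, j)
            sy = np.full(j, 0.01)
            x = gamma + rng.normal(0, 0.002, j)
            y = theta * gamma + rng.normal(0, sy)
            h = make_harmonised(x, y, sy)
            if egger(h).intercept_pvalue < 0.05:
                rejections += 1
        rate = rejections / reps
        # 2 binomial SEs around 0.05 at 400 reps is ~0.022
        assert 0.02 < rate < 0.09


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        h = make_harmonised([1.0, 1.0, 1.0], [0.1, 0.5, 0.9], [0.1] * 3)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_exhaustive_cdf_interpolation_oracle(self):
        x = np.array([0.5, 1.0, 0.8, 1.2])
        y = np.array([0.2, 0.55, 0.32, 0.78])
        sy = np.array([0.05, 0.04, 0.08, 0.05])
        h = make_harmonised(x, y, sy)
        est = weighted_median(h, n_boot=200, seed=1)
        # oracle: walk the weighted empirical CDF by hand
        ratios = y / x
        weights = x**2 / sy**2
        order = np.argsort(ratios)
        r_s, w_s = ratios[order], weights[order]
        w_s = w_s / w_s.sum()
        cum = np.cumsum(w_s) - 0.5 * w_s
        expected = None
        for i in range(1, len(r_s)):
            if cum[i - 1] <= 0.5 <= cum[i]:
                frac = (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
                expected = r_s[i - 1] + frac * (r_s[i] - r_s[i - 1])
                break
        assert expected is not None
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_robust_to_forty_percent_invalid_instruments(self):
        rng = np.random.default_rng(7)
        theta = 0.5
        reps = 40
        median_hits, ivw_hits = [], []
        for _ in range(reps):
            j = 10
            gamma = rng.uniform(0.1, 0.3, j)
            sy = np.full(j, 0.001)  # precise ratios so the valid cluster is tight
            bias = np.zeros(j)
            bias[:4] = 0.05  # 40% invalid, shared directional bias
            y = theta * gamma + bias + rng.normal(0, sy)
            h = make_harmonised(gamma, y, sy)
            median_hits.append(weighted_median(h, n_boot=100, seed=3).beta)
            ivw_hits.append(ivw(h).beta)
        mean = np.mean(median_hits)
        mcse = np.std(median_hits) / np.sqrt(reps)
        assert abs(mean - theta) < 2 * mcse + 0.01
        # IVW is visibly displaced by the shared bias, the median is not
        assert abs(np.mean(ivw_hits) - theta) > 3 * abs(mean - theta)

    def test_correlated_variants_rejected(self):
        r = np.array([[1.0, 0.7, 0.0], [0.7, 1.0, 0.0], [0.0, 0.0, 1.0]])
        h = make_harmonised([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.01] * 3, ld=r)
        with pytest.raises(EstimatorError, match="rs1.*rs2"):
            weighted_median(h, n_boot=100, seed=0)

    def test_bootstrap_se_reproducible_with_seed(self):
        h = make_harmonised([0.5, 1.0, 0.8], [0.2, 0.55, 0.32],
                            [0.05, 0.04, 0.08], sx=[0.01, 0.01, 0.01])
        e1 = weighted_median(h, n_boot=500, seed=42)
        e2 = weighted_median(h, n_boot=500, seed=42)
        assert e1.se == e2.se


class TestModeBased:
    def test_identical_ratios_return_common_value(self):
        x = np.array([0.1, 0.2, 0.4])
        h = make_harmonised(x, 0.5 * x, [0.01] * 3)
        est = mode_based(h, n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-9)

    def test_mode_tracks_majority_cluster(self):
        # 7 ratios near 0.3, 3 near 1.0; the mode should sit near 0.3
        x = np.ones(10)
        y = np.array([0.29, 0.3, 0.31, 0.3, 0.28, 0.32, 0.3, 0.98, 1.0, 1.02])
        h = make_harmonised(x, y, np.full(10, 0.05))
        est = mode_based(h, n_boot=100, seed=0)
        assert abs(est.beta - 0.3) < 0.05

    def test_matches_fine_grid_density_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.2, 0.5, 8)
        y = 0.4 * x + rng.normal(0, 0.02, 8)
        sy = rng.uniform(0.02, 0.05, 8)
        h = make_harmonised(x, y, sy)
        for weighted in (True, False):
            est = mode_based(h, weighted=weighted, n_boot=50, seed=0)
            ratios = y / x
            w = (x / sy) ** 2 if weighted else np.ones(8)
            sd = np.std(ratios, ddof=1)
            mad = np.median(np.abs(ratios - np.median(ratios))) / stats.norm.ppf(0.75)
            bw = 0.9 * min(sd, mad) * 8 ** (-0.2)
            grid = np.linspace(ratios.min() - 2 * bw, ratios.max() + 2 * bw, 200001)
            dens = np.zeros_like(grid)
            for rj, wj in zip(ratios, w):
                dens += wj * np.exp(-0.5 * ((grid - rj) / bw) ** 2)
            oracle = grid[np.argmax(dens)]
            assert est.beta == pytest.approx(oracle, abs=2e-4)

    def test_larger_phi_smooths_toward_weighted_centre(self):
        x = np.ones(10)
        y = np.array([0.29, 0.3, 0.31, 0.3, 0.28, 0.32, 0.3, 0.98, 1.0, 1.02])
        h = make_harmonised(x, y, np.full(10, 0.05))
        tight = mode_based(h, phi=1.0, n_boot=50, seed=0).beta
        smooth = mode_based(h, phi=20.0, n_boot=50, seed=0).beta
        assert tight < smooth < 1.0  # pulled between the two clusters


class TestRobust:
    def test_clean_data_matches_fixed_effects_ivw(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0.1, 0.4, 12)
        y = -0.5 * x + rng.normal(0, 0.002, 12)
        sy = np.full(12, 0.01)
        h = make_harmonised(x, y, sy)
        r = robust(h)
        f = ivw(h, "fixed")
        assert r.beta == pytest.approx(f.beta, abs=1e-3)

    def test_outlier_downweighted_and_estimate_unmoved(self):
        rng = np.random.default_rng(9)
        j, theta = 20, -0.5
        x = rng.uniform(0.1, 0.4, j)
        sy = np.full(j, 0.01)
        y = theta * x + rng.normal(0, sy)
        y[5] = theta * x[5] * 10  # gross outlier
        h = make_harmonised(x, y, sy)
        r = robust(h)
        f = ivw(h, "fixed")
        assert abs(r.beta - theta) < 0.05
        assert abs(f.beta - theta) > abs(r.beta - theta)
        assert r.weights[5] < 0.01


class TestCochranQ:
    def test_perfect_fit(self):
        x = np.array([0.1, 0.2, 0.4])
        h = make_harmonised(x, 0.5 * x, [0.01] * 3)
        q, df, p = cochran_q(h, 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_hand_computed_weighted_residual_sum(self):
        x = np.array([0.1, 0.2, 0.3])
        y = np.array([0.05, 0.12, 0.14])
        sy = np.array([0.01, 0.02, 0.015])
        h = make_harmonised(x, y, sy)
        beta = 0.5
        expected = sum(
            (yi - beta * xi) ** 2 / si**2 for xi, yi, si in zip(x, y, sy)
        )
        q, df, _ = cochran_q(h, beta)
        assert q == pytest.approx(expected, rel=1e-12)

    def test_null_distribution_is_chi_square(self):
        rng = np.random.default_rng(31)
        j, theta = 30, 0.4
        qs = []
        for _ in range(500) :
            gamma = rng.uniform(0.1, 0.3, j)
            sy = np.full(j, 0.01)
            y = theta * gamma + rng.normal(0, sy)
            h = make_harmonised(gamma, y, sy)
            qs.append(ivw(h).q_statistic)
        # chi-square(29): mean 29, sd sqrt(58); MC error of the mean ~0.34
        assert np.mean(qs) == pytest.approx(29, abs=3 * np.sqrt(58 / 500))

    def test_egger_degrees_of_freedom(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([0.03, 0.12, 0.14, 0.21])
        h = make_harmonised(x, y, [0.01] * 4)
        _, df, _ = cochran_q(h, 0.5, intercept=0.01)
        assert df == 2


class TestEstimatorAgreement:
    def test_all_methods_agree_on_clean_strong_data(self):
        rng = np.random.default_rng(100)
        j, theta = 30, -0.4
        gamma = rng.uniform(0.1, 0.3, j)
        sy = np.full(j, 0.005)
        x = gamma + rng.normal(0, 0.001, j)
        y = theta * gamma + rng.normal(0, sy)
        h = make_harmonised(x, y, sy, sx=np.full(j, 0.001))
        estimates = {
            "ivw": ivw(h).beta,
            "egger": egger(h).beta,
            "median": weighted_median(h, n_boot=200, seed=0).beta,
            "mode": mode_based(h, n_boot=50, seed=0).beta,
            "robust": robust(h).beta,
        }
        for name, value in estimates.items():
            assert abs(value - theta) < 0.05, name
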