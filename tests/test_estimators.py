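"""Estimator suite: Wald, IVW, Egger, weighted median/mode, OR reporting."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrscreen import estimators
from mrscreen.estimators import (
    egger,
    ivw,
    to_odds_ratio,
    wald_ratios,
    weighted_median,
    weighted_mode,
)
from mrscreen.synthetic_data import simulate_pair

from conftest import make_pair


class TestWaldRatios:
    def test_direct_evaluation(self):
        pair = make_pair([0.5], [0.05], [0.25], [0.05])
        r, s = wald_ratios(pair)
        assert r[0] == pytest.approx(0.5)
        assert s[0] == pytest.approx(0.1)

    def test_negative_gamma_sign(self):
        pair = make_pair([-0.5], [0.05], [0.25], [0.05])
        r, _ = wald_ratios(pair)
        assert r[0] == pytest.approx(-0.5)

    def test_zero_gamma_errors_naming_variant(self):
        pair = make_pair([0.5, 0.0], [0.05] * 2, [0.25, 0.1], [0.05] * 2)
        with pytest.raises(ValueError, match="rs2"):
            wald_ratios(pair)


class TestIVW:
    def test_homogeneous_ratios_degenerate(self, homogeneous_pair):
        est = ivw(homogeneous_pair)
        assert est.beta == pytest.approx(0.3)
        assert est.extras["sigma_hat"] == pytest.approx(0.0, abs=1e-8)
        assert est.se == pytest.approx(est.extras["se_fixed"])

    def test_matches_wls_oracle(self, rng):
        # independent oracle: QR least squares on sqrt(w)-scaled variables
        for _ in range(10):
            J = rng.integers(3, 12)
            g = rng.normal(0.2, 0.05, J)
            G = rng.normal(0.05, 0.03, J)
            sy = rng.uniform(0.01, 0.05, J)
            pair = make_pair(g, np.full(J, 0.01), G, sy)
            est = ivw(pair, effects_model="fixed")
            sw = 1.0 / sy
            beta_hat, *_ = np.linalg.lstsq((sw * g)[:, None], sw * G, rcond=None)
            assert est.beta == pytest.approx(float(beta_hat[0]), abs=1e-12)
            se_fixed = 1.0 / np.linalg.norm(sw * g)
            assert est.se == pytest.approx(se_fixed, abs=1e-12)

    def test_normal_equation_residual(self, rng):
        g = rng.normal(0.2, 0.05, 20)
        G = 0.3 * g + rng.normal(0, 0.02, 20)
        sy = rng.uniform(0.01, 0.05, 20)
        pair = make_pair(g, np.full(20, 0.01), G, sy)
        est = ivw(pair)
        w = 1 / sy**2
        assert abs(np.sum(w * g * (G - est.beta * g))) < 1e-10

    def test_underdispersion_floors_at_fixed_se(self):
        # near-identical ratios: sigma_hat << 1, SE must equal the fixed SE
        g = np.array([0.2, 0.3, 0.4, 0.5])
        G = 0.3 * g + np.array([1e-6, -1e-6, 1e-6, -1e-6])
        pair = make_pair(g, np.full(4, 0.01), G, np.full(4, 0.02))
        est = ivw(pair)
        assert est.extras["sigma_hat"] < 1
        assert est.se == pytest.approx(est.extras["se_fixed"])

    def test_too_few_instruments(self):
        with pytest.raises(ValueError, match="at least 2"):
            ivw(make_pair([0.1], [0.01], [0.05], [0.02]))


class TestEgger:
    def test_noiseless_line_recovered(self):
        g = np.array([0.2, 0.3, 0.4, 0.5, 0.7])
        G = 0.1 + 0.2 * g
        pair = make_pair(g, np.full(5, 0.01), G, np.full(5, 0.02))
        est = egger(pair)
        assert est.extras["intercept"] == pytest.approx(0.1, abs=1e-10)
        assert est.beta == pytest.approx(0.2, abs=1e-10)
        assert est.extras["sigma_hat"] == pytest.approx(0.0, abs=1e-6)

    def test_orientation_invariance(self, rng):
        # flipping the sign of (gamma, Gamma) at some variants changes nothing
        g = rng.normal(0.3, 0.05, 10)
        G = 0.05 + 0.2 * g + rng.normal(0, 0.01, 10)
        pair = make_pair(g, np.full(10, 0.01), G, np.full(10, 0.02))
        flip = rng.random(10) < 0.5
        s = np.where(flip, -1.0, 1.0)
        pair2 = make_pair(g * s, np.full(10, 0.01), G * s, np.full(10, 0.02))
        e1, e2 = egger(pair), egger(pair2)
        assert e1.beta == pytest.approx(e2.beta)
        assert e1.extras["intercept"] == pytest.approx(e2.extras["intercept"])

    def test_two_instruments_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            egger(make_pair([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2))


class TestWeightedMedian:
    def test_equal_weight_midpoint_formula(self):
        g = np.array([1.0, 1.0, 1.0])
        G = np.array([0.1, 0.2, 0.3])
        pair = make_pair(g, np.full(3, 0.01), G, np.full(3, 0.05))
        est = weighted_median(pair, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_robust_to_30pct_invalid(self):
        # 70% of instruments have ratio 0.2, 30% shifted to 1.0
        rng = np.random.default_rng(42)
        J = 20
        g = rng.uniform(0.2, 0.5, J)
        true = np.full(J, 0.2)
        true[:6] = 1.0
        G = true * g + rng.normal(0, 0.002, J)
        pair = make_pair(g, np.full(J, 0.002), G, np.full(J, 0.005))
        wm = weighted_median(pair, n_boot=200, seed=1)
        iv = ivw(pair)
        assert abs(wm.beta - 0.2) < 0.05
        assert abs(iv.beta - 0.2) > 0.05

    def test_bootstrap_se_deterministic(self, homogeneous_pair):
        a = weighted_median(homogeneous_pair, n_boot=300, seed=9)
        b = weighted_median(homogeneous_pair, n_boot=300, seed=9)
        assert a.se == b.se


class TestWeightedMode:
    def test_degenerate_cluster(self):
        g = np.array([0.2, 0.3, 0.4])
        pair = make_pair(g, np.full(3, 0.01), 0.25 * g, np.full(3, 0.02))
        est = weighted_mode(pair, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.25)

    def test_majority_cluster_found(self):
        rng = np.random.default_rng(7)
        J = 10
        g = rng.uniform(0.3, 0.6, J)
        true = np.full(J, 0.2)
        true[:4] = rng.uniform(0.6, 1.8, 4)  # dispersed invalid minority
        G = true * g + rng.normal(0, 0.001, J)
        pair = make_pair(g, np.full(J, 0.002), G, np.full(J, 0.004))
        est = weighted_mode(pair, n_boot=100, seed=1)
        assert abs(est.beta - 0.2) < 0.05

    @pytest.mark.parametrize("phi", [0.5, 1.0, 2.0, 4.0])
    def test_estimate_stays_in_ratio_range(self, phi, rng):
        g = rng.uniform(0.2, 0.5, 8)
        G = rng.normal(0.1, 0.05, 8)
        pair = make_pair(g, np.full(8, 0.01), G, np.full(8, 0.02))
        ratios, _ = wald_ratios(pair)
        est = weighted_mode(pair, phi=phi, n_boot=100, seed=1)
        assert ratios.min() <= est.beta <= ratios.max()


class TestOddsRatio:
    def test_null_effect(self):
        est = estimators._finish("ivw_re", 0.0, 0.05, 1.0, 10)
        to_odds_ratio(est)
        assert est.or_ == pytest.approx(1.0)
        assert est.or_ci_low * est.or_ci_high == pytest.approx(1.0)

    def test_direct_evaluation(self):
        est = estimators._finish("ivw_re", 0.1, 0.05, 0.05, 10)
        to_odds_ratio(est)
        assert est.or_ == pytest.approx(1.10517, abs=1e-5)
        assert est.or_ci_low == pytest.approx(1.00210, abs=1e-4)
        # exp(0.1 + 1.96*0.05) = exp(0.198)
        assert est.or_ci_high == pytest.approx(1.21896, abs=1e-4)
        assert est.or_ci_low > 0


class TestCrossEstimatorProperties:
    def test_single_shared_ratio_consensus(self, homogeneous_pair):
        vals = [
            ivw(homogeneous_pair).beta,
            egger(homogeneous_pair).beta,
            weighted_median(homogeneous_pair, n_boot=100, seed=1).beta,
            weighted_mode(homogeneous_pair, n_boot=100, seed=1).beta,
        ]
        np.testing.assert_allclose(vals, 0.3, atol=1e-8)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, c, rng):
        g = rng.normal(0.3, 0.05, 12)
        G = 0.2 * g + rng.normal(0, 0.01, 12)
        sy = rng.uniform(0.01, 0.03, 12)
        pair1 = make_pair(g, np.full(12, 0.01), G, sy)
        pair2 = make_pair(g, np.full(12, 0.01), c * G, c * sy)
        for fn in (lambda p: ivw(p), lambda p: egger(p)):
            e1, e2 = fn(pair1), fn(pair2)
            assert e2.beta == pytest.approx(c * e1.beta)
            assert e2.se == pytest.approx(c * e1.se)

    def test_egger_matches_statsmodels_oracle(self, rng):
        g = np.abs(rng.normal(0.3, 0.05, 15))
        G = 0.05 + 0.2 * g + rng.normal(0, 0.02, 15)
        sy = rng.uniform(0.01, 0.05, 15)
        pair = make_pair(g, np.full(15, 0.01), G, sy)
        est = egger(pair)
        fit = sm.WLS(G, sm.add_constant(g), weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-12)
        assert est.extras["intercept"] == pytest.approx(fit.params[0], abs=1e-12)
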