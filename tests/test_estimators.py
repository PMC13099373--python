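"""Estimator suite: closed forms, independent least-squares oracles,
robustness properties."""

import numpy as np
import pytest

from vadmr.estimators import (
    EstimatorError,
    cochran_q,
    egger,
    f_statistic,
    ivw,
    ivw_correlated,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from vadmr.synthetic import simulate_ld

from conftest import gls_oracle, ivw_wls_oracle


class TestWaldRatio:
    def test_closed_form(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        est = wald_ratio(0.1, 0.01, 0.0, 0.01)
        assert est.beta == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_second_order_delta_method(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01, second_order=True)
        # se^2 = sey^2/bx^2 + by^2 sex^2/bx^4; equivalently
        # |beta| * sqrt(sey^2/by^2 + sex^2/bx^2) for the ratio
        expected = 0.5 * np.sqrt(0.01**2 / 0.05**2 + 0.01**2 / 0.1**2)
        assert est.se == pytest.approx(expected, abs=1e-12)
        assert est.se == pytest.approx(0.11180339887498948)

    def test_zero_bx_is_error(self):
        with pytest.raises(EstimatorError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


class TestIvw:
    def test_two_instrument_closed_form(self):
        est = ivw([0.1, 0.2], [0.01, 0.01], [0.05, 0.08], [0.01, 0.02],
                  random_effects=False)
        assert est.beta == pytest.approx(0.45)
        assert est.se == pytest.approx(1 / np.sqrt(200))

    def test_single_instrument_reduces_to_wald(self):
        est = ivw([0.1], [0.01], [0.05], [0.01], random_effects=False)
        wald = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_identical_ratios_give_zero_q(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = ivw(bx, bx * 0 + 0.01, 0.4 * bx, [0.01, 0.01, 0.01])
        assert est.beta == pytest.approx(0.4)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = rng.integers(2, 12)
            bx = rng.normal(0.1, 0.05, n)
            by = rng.normal(0.0, 0.1, n)
            sey = rng.uniform(0.01, 0.2, n)
            est = ivw(bx, np.full(n, 0.01), by, sey, random_effects=False)
            beta_o, se_o = ivw_wls_oracle(bx, by, sey)
            assert est.beta == pytest.approx(beta_o, abs=1e-10)
            assert est.se == pytest.approx(se_o, abs=1e-10)

    def test_random_effects_escalation_inflates_se_only(self):
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        by = np.array([0.01, 0.09, -0.05, 0.12])  # heterogeneous ratios
        sey = np.full(4, 0.01)
        fe = ivw(bx, bx * 0 + 0.01, by, sey, random_effects=False)
        auto = ivw(bx, bx * 0 + 0.01, by, sey, random_effects="auto")
        assert auto.method == "ivw_mre"
        assert auto.beta == pytest.approx(fe.beta)
        assert auto.se > fe.se


class TestIvwCorrelated:
    def test_identity_correlation_equals_ivw(self):
        bx, by = np.array([0.1, 0.2, 0.15]), np.array([0.05, 0.08, 0.06])
        sey = np.array([0.01, 0.02, 0.015])
        fe = ivw(bx, bx * 0, by, sey, random_effects=False)
        corr = ivw_correlated(bx, bx * 0, by, sey, np.eye(3))
        assert corr.beta == pytest.approx(fe.beta, abs=1e-12)
        assert corr.se == pytest.approx(fe.se, abs=1e-12)

    def test_duplicated_instrument_recovers_wald(self):
        # perfectly correlated duplicate carries no extra information
        rho = np.array([[1.0, 1.0], [1.0, 1.0]])
        est = ivw_correlated(
            [0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.01, 0.01], rho, ridge=1e-6
        )
        wald = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(wald.beta, rel=1e-4)
        assert est.se == pytest.approx(wald.se, rel=1e-3)

    def test_matches_gls_oracle_under_ar1_ld(self):
        rng = np.random.default_rng(7)
        rho = simulate_ld(3, 0.5).r
        for _ in range(100):
            bx = rng.normal(0.1, 0.05, 3)
            by = rng.normal(0.05, 0.05, 3)
            sey = rng.uniform(0.01, 0.1, 3)
            est = ivw_correlated(bx, bx * 0, by, sey, rho)
            beta_o, se_o = gls_oracle(bx, by, sey, rho)
            assert est.beta == pytest.approx(beta_o, abs=1e-10)
            assert est.se == pytest.approx(se_o, abs=1e-10)

    def test_singular_covariance_raises_with_hint(self):
        rho = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(EstimatorError, match="ridge"):
            ivw_correlated([0.1, 0.1], [0, 0], [0.05, 0.05], [0.01, 0.01], rho)


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.02 + 0.4 * bx
        res = egger(bx, np.full(3, 0.01), by, np.full(3, 0.01))
        assert res.beta == pytest.approx(0.4, abs=1e-10)
        assert res.intercept == pytest.approx(0.02, abs=1e-10)

    def test_bx_orientation_flip(self):
        # flipping a row's signs must not change the fit
        bx = np.array([0.1, -0.2, 0.3])
        by = np.array([0.06, -0.10, 0.14])
        res = egger(bx, np.full(3, 0.01), by, np.full(3, 0.01))
        res_flipped = egger(np.abs(bx), np.full(3, 0.01),
                            by * np.sign(bx), np.full(3, 0.01))
        assert res.beta == pytest.approx(res_flipped.beta)
        assert res.intercept == pytest.approx(res_flipped.intercept)

    def test_too_few_instruments(self):
        with pytest.raises(EstimatorError):
            egger([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.01, 0.01])

    def test_collinear_design_is_error(self):
        with pytest.raises(EstimatorError, match="collinear"):
            egger([0.1, 0.1, 0.1], [0.01] * 3, [0.04, 0.05, 0.06], [0.01] * 3)

    def test_balanced_pleiotropy_intercept_near_zero(self):
        # symmetric direct effects: intercept should not be detected
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(50):
            bx = rng.uniform(0.05, 0.3, 20)
            alpha = rng.normal(0, 0.01, 20)  # balanced, mean zero
            by = 0.5 * bx + alpha + rng.normal(0, 0.005, 20)
            res = egger(bx, np.full(20, 0.01), by, np.full(20, 0.012))
            hits += res.intercept_pvalue < 0.05
        assert hits <= 10  # ~5% nominal, generous Monte-Carlo band


class TestWeightedMedian:
    def test_equal_weight_interpolation(self):
        est = weighted_median([1, 1, 1], [0.01] * 3, [0.4, 0.5, 0.6], [0.1] * 3,
                              n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_all_ratios_equal(self):
        est = weighted_median([0.1, 0.2, 0.4], [0.01] * 3,
                              [0.05, 0.10, 0.20], [0.001] * 3, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-9)
        assert est.se < 0.05

    def test_breakdown_resists_one_outlier(self):
        bx = np.full(10, 0.2)
        by = np.full(10, 0.1)  # ratios 0.5
        by[0] = 1.0  # wild outlier ratio 5.0
        est = weighted_median(bx, np.full(10, 0.01), by, np.full(10, 0.01),
                              n_boot=100, seed=3)
        assert abs(est.beta - 0.5) < 0.05

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.1, 0.3, 7)
        by = rng.normal(0.1, 0.05, 7)
        sey = rng.uniform(0.01, 0.05, 7)
        a = weighted_median(bx, bx * 0, by, sey, n_boot=10, seed=0)
        perm = rng.permutation(7)
        b = weighted_median(bx[perm], bx[perm] * 0, by[perm], sey[perm],
                            n_boot=10, seed=0)
        assert a.beta == pytest.approx(b.beta)

    def test_weight_splitting_invariance(self):
        # duplicating an instrument with its weight halved keeps the estimate
        bx = np.array([0.1, 0.2, 0.3])
        by = np.array([0.04, 0.11, 0.15])
        sey = np.array([0.01, 0.02, 0.015])
        a = weighted_median(bx, bx * 0, by, sey, n_boot=10, seed=0)
        bx2 = np.array([0.1, 0.2, 0.3, 0.3])
        by2 = np.array([0.04, 0.11, 0.15, 0.15])
        sey2 = np.array([0.01, 0.02, 0.015 * np.sqrt(2), 0.015 * np.sqrt(2)])
        b = weighted_median(bx2, bx2 * 0, by2, sey2, n_boot=10, seed=0)
        assert a.beta == pytest.approx(b.beta)


class TestCochranQ:
    def test_identical_ratios(self):
        q, df, p = cochran_q([0.1, 0.2], [0, 0], [0.04, 0.08], [0.01, 0.01], 0.4)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # equal weights 100, ratios 0.4 and 0.6 around beta 0.5
        q, df, _ = cochran_q([0.1, 0.1], [0, 0], [0.04, 0.06], [0.01, 0.01], 0.5)
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_q_grows_with_heterogeneous_instrument(self):
        q1, _, _ = cochran_q([0.1, 0.1], [0, 0], [0.05, 0.05], [0.01, 0.01], 0.5)
        q2, _, _ = cochran_q([0.1, 0.1, 0.1], [0, 0, 0], [0.05, 0.05, 0.09],
                             [0.01, 0.01, 0.01], 0.5)
        assert q2 > q1


class TestOddsRatio:
    def test_conversion_and_round_trip(self):
        est = ivw([0.1, 0.2], [0, 0], [-0.0105, -0.021], [0.008, 0.016],
                  random_effects=False)
        est.scale = "log-odds"
        orred = to_odds_ratio(est)
        assert orred.beta == pytest.approx(np.exp(est.beta))
        assert orred.ci_low == pytest.approx(np.exp(est.ci_low))
        assert orred.pvalue == est.pvalue
        assert np.log(orred.beta) == pytest.approx(est.beta)

    def test_published_style_interval(self):
        # log-odds -0.105 (se 0.061) prints as OR 0.90, CI 0.80-1.01
        est = wald_ratio(1.0, 0.0, -0.105, 0.061)
        est.scale = "log-odds"
        orred = to_odds_ratio(est)
        assert orred.beta == pytest.approx(0.90, abs=0.005)
        assert orred.ci_low == pytest.approx(0.80, abs=0.005)
        assert orred.ci_high == pytest.approx(1.01, abs=0.005)

    def test_linear_scale_rejected(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01)
        with pytest.raises(EstimatorError):
            to_odds_ratio(est)


def test_f_statistic_rules():
    f, summary, weak = f_statistic([0.1], [0.01])
    assert f[0] == pytest.approx(100.0) and summary == 100.0 and not weak
    # threshold is strict <: mean of 4 and 16 is exactly 10 -> not weak
    _, summary, weak = f_statistic([0.02, 0.04], [0.01, 0.01])
    assert summary == pytest.approx(10.0) and not weak
    _, summary, weak = f_statistic([0.0], [0.01])
    assert summary == 0.0 and weak
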