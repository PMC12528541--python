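"""MR estimators against independent oracles and exact reductions."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrmediate.estimators import egger, ivw, wald_ratio, weighted_median

from conftest import make_pairs


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(dict(beta_exp=0.5, beta_out=0.25, se_out=0.1))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome_effect(self):
        est = wald_ratio(dict(beta_exp=0.5, beta_out=0.0, se_out=0.1))
        assert est.beta == 0.0 and est.pvalue == 1.0

    def test_ratio_invariant_to_joint_sign_flip(self):
        a = wald_ratio(dict(beta_exp=0.5, beta_out=0.25, se_out=0.1))
        b = wald_ratio(dict(beta_exp=-0.5, beta_out=-0.25, se_out=0.1))
        assert (a.beta, a.se, a.pvalue) == (b.beta, b.se, b.pvalue)

    def test_zero_exposure_effect_is_an_error(self):
        with pytest.raises(ValueError):
            wald_ratio(dict(beta_exp=0.0, beta_out=0.1, se_out=0.1))


class TestIVW:
    def test_single_pair_reduces_to_wald(self):
        pairs = make_pairs([0.5], [0.25], [0.1])
        est = ivw(pairs)
        w = wald_ratio(pairs.iloc[0])
        assert est.beta == pytest.approx(w.beta, rel=1e-15)
        assert est.se == pytest.approx(w.se, rel=1e-15)

    def test_common_ratio_recovered_with_zero_heterogeneity(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        est = ivw(make_pairs(bx, 0.7 * bx, [0.05, 0.04, 0.03, 0.06]))
        assert est.beta == pytest.approx(0.7, rel=1e-12)
        assert est.extra["Q"] == pytest.approx(0.0, abs=1e-18)
        assert est.se == pytest.approx(est.extra["se_fixed"], rel=1e-12)

    def test_matches_weighted_least_squares_through_origin(self):
        rng = np.random.default_rng(8)
        bx = rng.normal(0.2, 0.1, 8)
        by = rng.normal(0.1, 0.2, 8)
        sy = rng.uniform(0.02, 0.2, 8)
        est = ivw(make_pairs(bx, by, sy))
        # independent normal-equations oracle
        w = 1.0 / sy**2
        oracle = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        assert est.beta == pytest.approx(oracle, rel=1e-12)

    def test_invariant_to_pair_order(self):
        rng = np.random.default_rng(3)
        bx = rng.normal(0.2, 0.1, 10)
        by = rng.normal(0.1, 0.2, 10)
        sy = rng.uniform(0.02, 0.2, 10)
        pairs = make_pairs(bx, by, sy)
        shuffled = pairs.sample(frac=1, random_state=1).reset_index(drop=True)
        a, b = ivw(pairs), ivw(shuffled)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            ivw(make_pairs([], [], []))


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        slope, intercept = egger(make_pairs(bx, 0.6 * bx, np.full(5, 0.05)))
        assert slope.beta == pytest.approx(0.6, rel=1e-10)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_constant_pleiotropy_lands_in_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        slope, intercept = egger(make_pairs(bx, 0.6 * bx + 0.05, np.full(5, 0.05)))
        assert intercept.beta == pytest.approx(0.05, rel=1e-10)
        assert slope.beta == pytest.approx(0.6, rel=1e-10)

    def test_matches_statsmodels_wls_oracle(self):
        rng = np.random.default_rng(4)
        bx = np.abs(rng.normal(0.2, 0.1, 7))
        by = rng.normal(0.1, 0.1, 7)
        sy = rng.uniform(0.02, 0.2, 7)
        slope, intercept = egger(make_pairs(bx, by, sy))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert slope.beta == pytest.approx(fit.params[1], rel=1e-10)
        assert intercept.beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_negative_exposure_effects_oriented_first(self):
        rng = np.random.default_rng(5)
        bx = rng.normal(0.0, 0.2, 6)
        by = 0.4 * bx + rng.normal(0, 0.02, 6)
        sy = np.full(6, 0.05)
        slope_mixed, _ = egger(make_pairs(bx, by, sy))
        slope_pos, _ = egger(make_pairs(np.abs(bx), np.sign(bx) * by, sy))
        assert slope_mixed.beta == pytest.approx(slope_pos.beta, rel=1e-12)

    def test_directional_pleiotropy_detected_by_intercept(self):
        """Planted mean-shifted pleiotropy pushes the intercept off zero."""
        from mrmediate.harmonize import harmonize, kept_pairs
        from mrmediate.synthetic import SimConfig, simulate_triple

        hits = 0
        n_rep = 40
        for s in range(n_rep):
            cfg = SimConfig(n_snps=30, n_mediator_snps=0, theta_total=0.0,
                            frac_pleiotropic=0.9, pleiotropy_mean=0.15,
                            pleiotropy_sd=0.02, frac_palindromic=0.0,
                            frac_strand_flipped=0.0, seed=900 + s)
            exp, _, out, _ = simulate_triple(cfg)
            pairs = kept_pairs(harmonize(exp, out)[0])
            _, intercept = egger(pairs)
            if intercept.pvalue < 0.05:
                hits += 1
        assert hits > n_rep / 2

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            egger(make_pairs([0.1, 0.2], [0.1, 0.1], [0.05, 0.05]))


class TestWeightedMedian:
    def test_equal_weights_gives_plain_median(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [1.0, 2.0, 9.0], [1.0, 1.0, 1.0])
        est = weighted_median(pairs, n_boot=100, seed=0)
        assert est.beta == pytest.approx(2.0, rel=1e-12)

    def test_dominant_central_weight_returns_its_ratio(self):
        # middle ratio holds >80% of the weight with the rest split evenly:
        # its cumulative midpoint sits exactly at 0.5, so it is returned
        sy = np.array([1.0, 1.0 / 3.0, 1.0])  # weights 1, 9, 1 with beta_exp = 1
        pairs = make_pairs([1.0, 1.0, 1.0], [1.0, 2.0, 9.0], sy)
        est = weighted_median(pairs, n_boot=100, seed=0)
        assert est.beta == pytest.approx(2.0, rel=1e-12)

    def test_matches_fine_grid_scan_of_cumulative_function(self):
        rng = np.random.default_rng(6)
        bx = np.abs(rng.normal(0.3, 0.1, 7))
        by = rng.normal(0.15, 0.1, 7)
        sy = rng.uniform(0.02, 0.2, 7)
        est = weighted_median(make_pairs(bx, by, sy), n_boot=100, seed=0)
        # oracle: dense scan over the piecewise-linear cumulative-weight curve
        r = by / bx
        w = bx**2 / sy**2
        order = np.argsort(r)
        r_s, w_s = r[order], w[order]
        s = (np.cumsum(w_s) - w_s / 2) / w_s.sum()
        grid = np.linspace(r_s[0], r_s[-1], 2_000_001)
        cum_at = np.interp(grid, r_s, s)
        oracle = grid[np.argmin(np.abs(cum_at - 0.5))]
        assert est.beta == pytest.approx(oracle, abs=2e-6)

    def test_bootstrap_reproducible_from_seed(self):
        rng = np.random.default_rng(7)
        pairs = make_pairs(
            np.abs(rng.normal(0.3, 0.1, 5)), rng.normal(0.1, 0.1, 5),
            rng.uniform(0.05, 0.2, 5),
        )
        a = weighted_median(pairs, n_boot=200, seed=11)
        b = weighted_median(pairs, n_boot=200, seed=11)
        c = weighted_median(pairs, n_boot=200, seed=12)
        assert a.se == b.se
        assert a.se != c.se

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            weighted_median(make_pairs([0.1], [0.1], [0.05]))


def test_all_estimators_agree_on_exact_proportional_data():
    bx = np.array([0.1, 0.25, 0.3, 0.45, 0.6])
    pairs = make_pairs(bx, -0.8 * bx, np.full(5, 0.05))
    assert ivw(pairs).beta == pytest.approx(-0.8, rel=1e-10)
    assert egger(pairs)[0].beta == pytest.approx(-0.8, rel=1e-10)
    assert weighted_median(pairs, n_boot=100, seed=0).beta == pytest.approx(-0.8, rel=1e-10)


def test_odds_ratio_columns_are_exact_exp_transforms():
    rng = np.random.default_rng(9)
    pairs = make_pairs(
        np.abs(rng.normal(0.3, 0.1, 6)), rng.normal(0.1, 0.1, 6),
        rng.uniform(0.05, 0.2, 6),
    )
    import math

    for est in [ivw(pairs), *egger(pairs), weighted_median(pairs, n_boot=50, seed=0)]:
        assert est.or_ == math.exp(est.beta)
        assert est.ci_low == math.exp(est.beta - est.crit * est.se)
        assert est.ci_high == math.exp(est.beta + est.crit * est.se)
        assert est.ci_low < est.or_ < est.ci_high
    assert ivw(pairs).crit == 1.96
    assert egger(pairs)[0].crit == pytest.approx(stats.t.ppf(0.975, 4))
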