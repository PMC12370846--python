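"""mr_estimators: the five methods against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
import statsmodels.api as sm

from mrchain.estimators import (
    EstimatorError,
    ivw,
    mode_estimators,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from mrchain.simulate import make_fixture

from conftest import mk_pairs, random_pairs


class TestWaldRatio:
    def test_beta(self):
        pair = mk_pairs([0.5], [0.1], [0.05])[0]
        res = wald_ratio(pair)
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)

    def test_negative_exposure_beta(self):
        pair = mk_pairs([-0.5], [0.1], [0.05])[0]
        res = wald_ratio(pair)
        assert res.beta == pytest.approx(-0.2)
        assert res.se == pytest.approx(0.1)  # |beta_exp| in the denominator

    def test_zero_exposure_beta_errors(self):
        with pytest.raises(EstimatorError):
            wald_ratio(mk_pairs([0.0], [0.1], [0.05])[0])

    def test_or_scale(self):
        res = wald_ratio(mk_pairs([0.5], [0.1], [0.05])[0])
        assert res.odds_ratio == pytest.approx(np.exp(res.beta))
        assert res.or_ci_low == pytest.approx(np.exp(res.ci_low))
        assert res.ci_low <= res.beta <= res.ci_high


def _wls_origin_oracle(pairs):
    """Independent WLS-through-origin via numpy lstsq on scaled variables."""
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    coef, *_ = np.linalg.lstsq((bx / sy)[:, None], by / sy, rcond=None)
    se_fixed = float(np.sum((bx / sy) ** 2)) ** -0.5
    beta = float(coef[0])
    ratios = by / bx
    w = bx ** 2 / sy ** 2
    q = float(np.sum(w * (ratios - beta) ** 2))
    scale = max(1.0, np.sqrt(q / (len(bx) - 1))) if len(bx) >= 2 else 1.0
    return beta, se_fixed, se_fixed * scale


class TestIVW:
    def test_single_snp_equals_wald(self):
        pairs = mk_pairs([0.5], [0.1], [0.05])
        res = ivw(pairs, "fixed")
        wald = wald_ratio(pairs[0])
        assert res.beta == wald.beta
        assert res.se == wald.se
        assert ivw(pairs, "multiplicative_random").beta == wald.beta

    def test_homogeneous_ratios_no_inflation(self):
        bx = [0.1, 0.2, 0.4]
        by = [0.03, 0.06, 0.12]  # every ratio exactly 0.3
        pairs = mk_pairs(bx, by, [0.01, 0.02, 0.01])
        fixed = ivw(pairs, "fixed")
        mre = ivw(pairs, "multiplicative_random")
        assert fixed.beta == pytest.approx(0.3, abs=1e-14)
        assert mre.se == fixed.se  # Q = 0 -> scale clamps at 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_wls_oracle(self, seed):
        pairs = random_pairs(np.random.default_rng(seed), 5 + seed % 4)
        beta, se_f, se_m = _wls_origin_oracle(pairs)
        fixed = ivw(pairs, "fixed")
        mre = ivw(pairs, "multiplicative_random")
        assert fixed.beta == pytest.approx(beta, abs=1e-10)
        assert fixed.se == pytest.approx(se_f, abs=1e-10)
        assert mre.beta == pytest.approx(beta, abs=1e-10)
        assert mre.se == pytest.approx(se_m, abs=1e-10)

    def test_equals_weighted_mean_of_ratios(self, rng):
        pairs = random_pairs(rng, 8)
        bx = np.array([p.beta_exp for p in pairs])
        by = np.array([p.beta_out for p in pairs])
        sy = np.array([p.se_out for p in pairs])
        w = bx ** 2 / sy ** 2
        expected = np.sum(w * (by / bx)) / np.sum(w)
        assert ivw(pairs, "fixed").beta == pytest.approx(expected, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(EstimatorError):
            ivw([])


class TestEgger:
    def test_exact_affine_data(self):
        pairs = make_fixture("egger_affine")
        res = mr_egger(pairs)
        assert res.intercept.estimate == pytest.approx(0.01, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.3, abs=1e-12)

    def test_two_snps_error(self):
        with pytest.raises(EstimatorError):
            mr_egger(mk_pairs([0.1, 0.2], [0.03, 0.06], [0.01, 0.01]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels_oracle(self, seed):
        pairs = random_pairs(np.random.default_rng(100 + seed), 6)
        bx = np.array([p.beta_exp for p in pairs])
        by = np.array([p.beta_out for p in pairs])
        sy = np.array([p.se_out for p in pairs])
        flip = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * flip, by * flip
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy ** 2).fit()
        sigma = np.sqrt(fit.scale)
        base_se = fit.bse / sigma
        expected_se = base_se * max(1.0, sigma)
        res = mr_egger(pairs)
        assert res.intercept.estimate == pytest.approx(fit.params[0], abs=1e-10)
        assert res.slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.intercept.se == pytest.approx(expected_se[0], abs=1e-10)
        assert res.slope.se == pytest.approx(expected_se[1], abs=1e-10)

    def test_orientation_invariance(self, rng):
        """Negating an exposure/outcome pair together changes nothing."""
        pairs = random_pairs(rng, 6)
        res_a = mr_egger(pairs)
        pairs[0].beta_exp *= -1
        pairs[0].beta_out *= -1
        res_b = mr_egger(pairs)
        assert res_a.slope.beta == pytest.approx(res_b.slope.beta, abs=1e-14)
        assert res_a.intercept.estimate == pytest.approx(
            res_b.intercept.estimate, abs=1e-14
        )


def _weighted_median_oracle(ratios, weights):
    """Definitional scan of the interpolated cumulative-weight function."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return r[0]
    for j in range(1, len(r)):
        if s[j] >= 0.5:
            frac = (0.5 - s[j - 1]) / (s[j] - s[j - 1])
            return r[j - 1] + frac * (r[j] - r[j - 1])
    return r[-1]


class TestWeightedMedian:
    def test_equal_weights_is_median(self):
        # ratios 0.1, 0.2, 0.9 with equal weights
        pairs = mk_pairs([0.1, 0.1, 0.1], [0.01, 0.02, 0.09],
                         [0.01, 0.01, 0.01])
        res = weighted_median(pairs, n_boot=50, seed=0)
        assert res.beta == pytest.approx(0.2)

    def test_identical_ratios_zero_spread(self):
        pairs = mk_pairs([0.1, 0.2, 0.3], [0.04, 0.08, 0.12],
                         [1e-8, 1e-8, 1e-8], sx=[1e-8, 1e-8, 1e-8])
        res = weighted_median(pairs, n_boot=100, seed=0)
        assert res.beta == pytest.approx(0.4)
        assert res.se < 1e-5

    def test_matches_definitional_oracle(self):
        pairs = make_fixture("median_seven")
        bx = np.array([p.beta_exp for p in pairs])
        by = np.array([p.beta_out for p in pairs])
        sy = np.array([p.se_out for p in pairs])
        expected = _weighted_median_oracle(by / bx, bx ** 2 / sy ** 2)
        res = weighted_median(pairs, n_boot=10, seed=0)
        assert res.beta == pytest.approx(expected, abs=1e-12)

    def test_too_few_instruments(self):
        with pytest.raises(EstimatorError):
            weighted_median(mk_pairs([0.1, 0.2], [0.03, 0.06], [0.01, 0.01]))

    def test_seed_determinism(self, rng):
        pairs = random_pairs(rng, 6)
        a = weighted_median(pairs, n_boot=200, seed=7)
        b = weighted_median(pairs, n_boot=200, seed=7)
        assert (a.beta, a.se) == (b.beta, b.se)


def _mode_density_oracle(ratios, weights, h):
    """Direct density evaluation on the same fixed grid."""
    grid = np.linspace(min(ratios) - 3 * h, max(ratios) + 3 * h, 512)
    dens = np.zeros_like(grid)
    for r, w in zip(ratios, weights):
        dens += w * np.exp(-0.5 * ((grid - r) / h) ** 2)
    return grid[np.argmax(dens)]


class TestModes:
    def test_identical_ratios(self):
        pairs = mk_pairs([0.1, 0.2, 0.4], [0.025, 0.05, 0.1],
                         [0.01, 0.01, 0.01])
        simple, weighted = mode_estimators(pairs, n_boot=10, seed=0)
        assert simple.beta == pytest.approx(0.25)
        assert weighted.beta == pytest.approx(0.25)
        assert simple.se == 0.0

    def test_majority_cluster(self):
        bx = [0.1] * 5
        by = [0.010, 0.010, 0.011, 0.009, 0.090]
        sy = [0.001] * 5
        pairs = mk_pairs(bx, by, sy)
        simple, weighted = mode_estimators(pairs, n_boot=20, seed=0)
        assert abs(simple.beta - 0.1) < 0.05
        assert abs(weighted.beta - 0.1) < 0.05
        # verify against direct density evaluation with the same bandwidth
        ratios = np.array(by) / np.array(bx)
        sd = np.std(ratios, ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25])) / 1.34
        h = 0.9 * min(sd, iqr if iqr > 0 else sd) * len(ratios) ** -0.2
        expected = _mode_density_oracle(ratios, [0.2] * 5, h)
        assert simple.beta == pytest.approx(expected, abs=1e-12)

    def test_determinism(self, rng):
        pairs = random_pairs(rng, 7)
        a = mode_estimators(pairs, n_boot=100, seed=3)
        b = mode_estimators(pairs, n_boot=100, seed=3)
        assert (a[0].beta, a[0].se, a[1].beta, a[1].se) == \
            (b[0].beta, b[0].se, b[1].beta, b[1].se)

    def test_too_few(self):
        with pytest.raises(EstimatorError):
            mode_estimators(mk_pairs([0.1], [0.02], [0.01]))


class TestEquivariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, rng, c):
        pairs = random_pairs(rng, 6)
        scaled = mk_pairs(
            [p.beta_exp for p in pairs],
            [c * p.beta_out for p in pairs],
            [c * p.se_out for p in pairs],
            sx=[p.se_exp for p in pairs],
        )
        for model in ("fixed", "multiplicative_random"):
            a, b = ivw(pairs, model), ivw(scaled, model)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-12)
            assert b.se == pytest.approx(c * a.se, rel=1e-12)
        ea, eb = mr_egger(pairs), mr_egger(scaled)
        assert eb.slope.beta == pytest.approx(c * ea.slope.beta, rel=1e-12)
        assert eb.slope.se == pytest.approx(c * ea.slope.se, rel=1e-12)
        ma = weighted_median(pairs, n_boot=50, seed=1)
        mb = weighted_median(scaled, n_boot=50, seed=1)
        assert mb.beta == pytest.approx(c * ma.beta, rel=1e-12)
        assert mb.se == pytest.approx(c * ma.se, rel=1e-9)

    def test_sign_equivariance(self, rng):
        pairs = random_pairs(rng, 6)
        negated = mk_pairs(
            [p.beta_exp for p in pairs],
            [-p.beta_out for p in pairs],
            [p.se_out for p in pairs],
            sx=[p.se_exp for p in pairs],
        )
        assert ivw(negated).beta == pytest.approx(-ivw(pairs).beta, rel=1e-12)
        assert mr_egger(negated).slope.beta == pytest.approx(
            -mr_egger(pairs).slope.beta, rel=1e-12
        )
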