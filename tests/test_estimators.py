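"""Causal estimators against closed forms and independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrmediate import (
    DegenerateInstrumentError,
    HarmonizedSet,
    InsufficientInstrumentsError,
    all_estimates,
    ivw,
    mode_estimate,
    mr_egger,
    to_odds_scale,
    wald_ratios,
    weighted_median,
)
from mrmediate.estimators import MREstimate


def hset(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    return HarmonizedSet.from_arrays(bx, sx, by, sy)


class TestWaldRatios:
    def test_closed_form(self):
        wr = wald_ratios(hset([0.5], [0.25], [0.1]))
        assert wr.ratio[0] == pytest.approx(0.5)
        assert wr.se[0] == pytest.approx(0.2)

    def test_negative_exposure_effect(self):
        wr = wald_ratios(hset([-0.5], [0.25], [0.1]))
        assert wr.ratio[0] == pytest.approx(-0.5)
        assert wr.se[0] == pytest.approx(0.2)  # SE uses |beta_exp|

    def test_scale_invariance_of_ratios(self):
        a = wald_ratios(hset([0.2, 0.3], [0.1, 0.15], [0.05, 0.05]))
        b = wald_ratios(hset([0.4, 0.6], [0.2, 0.3], [0.05, 0.05]))
        np.testing.assert_allclose(a.ratio, b.ratio)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratios(hset([0.0, 0.1], [0.1, 0.1], [0.1, 0.1]))


class TestIVW:
    def test_single_pair_reduces_to_wald(self):
        e = ivw(hset([0.5], [0.25], [0.1]))
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.2)

    def test_two_pair_closed_form(self):
        """Equal weights, beta_exp = 1: slope is the mean of the ratios."""
        e = ivw(hset([1.0, 1.0], [0.4, 0.6], [0.1, 0.1]), variant="fixed")
        assert e.beta == pytest.approx(0.5, abs=1e-12)
        # fixed SE = (sum w x^2)^{-1/2} = (2/0.01)^{-1/2}
        assert e.se == pytest.approx((2 / 0.01) ** -0.5, rel=1e-12)

    def test_matches_weighted_ls_oracle(self, toy_harmonized):
        """IVW slope == statsmodels WLS through the origin, to 1e-10."""
        sm = pytest.importorskip("statsmodels.api")
        bx, _, by, sy = toy_harmonized.arrays()
        fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
        ours = ivw(toy_harmonized, variant="fixed")
        assert ours.beta == pytest.approx(fit.params[0], abs=1e-10)
        # fixed SE strips the estimated scale statsmodels applies
        se_unit = fit.bse[0] / np.sqrt(fit.scale)
        assert ours.se == pytest.approx(se_unit, abs=1e-10)

    def test_random_equals_fixed_when_homogeneous(self, homogeneous_harmonized):
        f = ivw(homogeneous_harmonized, variant="fixed")
        r = ivw(homogeneous_harmonized, variant="random")
        assert r.beta == f.beta and r.se == f.se

    def test_random_never_below_fixed(self, toy_harmonized):
        f = ivw(toy_harmonized, variant="fixed")
        r = ivw(toy_harmonized, variant="random")
        assert r.se >= f.se

    def test_relabeling_invariance(self, toy_harmonized):
        perm = toy_harmonized.pairs.sample(frac=1, random_state=1).reset_index(
            drop=True
        )
        h2 = HarmonizedSet("e", "o", perm)
        assert ivw(h2).beta == pytest.approx(ivw(toy_harmonized).beta, rel=1e-12)


class TestEgger:
    def test_collinear_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3])
        res = mr_egger(hset(bx, 0.5 * bx, np.full(3, 0.05)))
        assert res.intercept.beta == pytest.approx(0.0, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.5, abs=1e-12)

    def test_constant_offset_recovered_as_intercept(self):
        bx = np.array([0.1, 0.25, 0.4, 0.6])
        c = 0.03
        res = mr_egger(hset(bx, 0.5 * bx + c, np.full(4, 0.05)))
        assert res.intercept.beta == pytest.approx(c, abs=1e-10)
        assert res.slope.beta == pytest.approx(0.5, abs=1e-10)

    def test_matches_wls_oracle_with_intercept(self, toy_harmonized):
        sm = pytest.importorskip("statsmodels.api")
        bx, _, by, sy = toy_harmonized.arrays()
        flip = np.sign(bx)
        X = np.column_stack([np.ones_like(bx), bx * flip])
        fit = sm.WLS(by * flip, X, weights=1 / sy**2).fit()
        ours = mr_egger(toy_harmonized)
        assert ours.intercept.beta == pytest.approx(fit.params[0], abs=1e-10)
        assert ours.slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        scale_ours = max(1.0, np.sqrt(fit.scale))
        assert ours.slope.se == pytest.approx(
            fit.bse[1] / np.sqrt(fit.scale) * scale_ours, abs=1e-10
        )

    def test_equal_se_equals_ols(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.1, 0.5, 6)
        by = 0.3 * bx + rng.normal(0, 0.02, 6)
        res = mr_egger(hset(bx, by, np.full(6, 0.04)))
        slope_ols, int_ols = np.polyfit(bx, by, 1)
        assert res.slope.beta == pytest.approx(slope_ols, abs=1e-10)
        assert res.intercept.beta == pytest.approx(int_ols, abs=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(hset([0.1, 0.2], [0.05, 0.1], [0.05, 0.05]))


class TestWeightedMedian:
    def test_equal_weights_interpolation_by_hand(self):
        """Ratios (1,2,3), equal weights: cumulative p = (1/6, 1/2, 5/6),
        interpolating to 0.5 gives exactly 2."""
        bx = np.full(3, 1.0)
        e = weighted_median(hset(bx, [1.0, 2.0, 3.0], np.full(3, 0.1)), n_boot=50)
        assert e.beta == pytest.approx(2.0, abs=1e-12)

    def test_asymmetric_interpolation_by_hand(self):
        """Equal weights, ratios (0, 1, 10): estimate stays 1 (median-like
        robustness to the outlying ratio)."""
        bx = np.full(3, 1.0)
        e = weighted_median(hset(bx, [0.0, 1.0, 10.0], np.full(3, 0.1)), n_boot=50)
        assert e.beta == pytest.approx(1.0, abs=1e-12)

    def test_dominant_weight_pins_estimate(self):
        # SNP 2 holds ~96% of the inverse-variance weight
        bx = np.array([1.0, 1.0, 1.0])
        sy = np.array([1.0, 1.0, 0.1])
        e = weighted_median(hset(bx, [0.0, 3.0, 1.0], sy), n_boot=50)
        assert e.beta == pytest.approx(1.0, abs=0.05)

    def test_bootstrap_se_deterministic_given_seed(self, toy_harmonized):
        a = weighted_median(toy_harmonized, n_boot=200, seed=3)
        b = weighted_median(toy_harmonized, n_boot=200, seed=3)
        assert a.se == b.se

    def test_min_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(hset([1.0], [0.5], [0.1]))


class TestMode:
    def test_cluster_dominates(self):
        bx = np.full(4, 1.0)
        e = mode_estimate(
            hset(bx, [1.0, 1.0, 1.0, 5.0], np.full(4, 0.2)), n_boot=50
        )
        assert e.beta == pytest.approx(1.0, abs=0.2)

    def test_degenerate_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        e = mode_estimate(hset(bx, 0.7 * bx, np.full(3, 0.05)), n_boot=50)
        assert e.beta == pytest.approx(0.7, abs=1e-12)

    def test_weighted_equals_simple_under_equal_weights(self):
        bx = np.full(5, 1.0)
        by = np.array([0.8, 1.0, 1.1, 1.2, 2.0])
        sy = np.full(5, 0.1)
        s = mode_estimate(hset(bx, by, sy), weighted=False, n_boot=50, seed=1)
        w = mode_estimate(hset(bx, by, sy), weighted=True, n_boot=50, seed=1)
        assert s.beta == pytest.approx(w.beta, abs=1e-12)

    def test_density_argmax_against_scipy_kde_grid(self):
        """Simple-mode point estimate tracks a scipy gaussian_kde argmax
        evaluated on the same grid and bandwidth."""
        from scipy.stats import gaussian_kde

        rng = np.random.default_rng(4)
        bx = np.full(12, 1.0)
        by = np.concatenate([rng.normal(1, 0.05, 9), rng.normal(3, 0.05, 3)])
        sy = np.full(12, 0.1)
        e = mode_estimate(hset(bx, by, sy), n_boot=50)
        ratios = by / bx
        j = len(ratios)
        sd = ratios.std(ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.349) * j ** (-0.2)
        kde = gaussian_kde(ratios, bw_method=h / sd)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
        oracle = grid[np.argmax(kde(grid))]
        assert e.beta == pytest.approx(oracle, abs=1e-9)


class TestOddsScale:
    def test_closed_form(self):
        e = to_odds_scale(MREstimate("ivw", 0.0, 0.1, 1.0, 3))
        assert e.or_ == pytest.approx(1.0)
        assert e.ci_low == pytest.approx(math.exp(-1.959964 * 0.1), rel=1e-12)
        assert e.ci_high == pytest.approx(math.exp(1.959964 * 0.1), rel=1e-12)

    def test_collapsing_ci_limit(self):
        e = to_odds_scale(MREstimate("ivw", math.log(2), 1e-12, 0.0, 3))
        assert e.or_ == pytest.approx(2.0, rel=1e-9)
        assert e.ci_high - e.ci_low < 1e-10

    def test_log_roundtrip_to_12_digits(self, toy_harmonized):
        e = ivw(toy_harmonized)
        assert math.log(e.or_) == pytest.approx(e.beta, abs=1e-12)
        assert e.ci_low < e.or_ < e.ci_high


class TestCrossMethod:
    def test_all_methods_agree_on_identical_ratios(self, homogeneous_harmonized):
        ests = all_estimates(homogeneous_harmonized, n_boot=50)
        betas = [e.beta for e in ests]
        np.testing.assert_allclose(betas, betas[0], atol=1e-10)

    def test_single_snp_yields_wald_only(self):
        ests = all_estimates(hset([0.5], [0.25], [0.1]))
        assert len(ests) == 1 and ests[0].method == "ivw"
        assert ests[0].beta == pytest.approx(0.5)

    @given(seed=st.integers(0, 10**6))
    def test_estimates_invariant_to_snp_relabeling(self, seed):
        rng = np.random.default_rng(seed % 1000)
        bx = rng.uniform(0.05, 0.4, 6)
        by = 0.4 * bx + rng.normal(0, 0.02, 6)
        sy = rng.uniform(0.02, 0.08, 6)
        h = hset(bx, by, sy)
        perm = rng.permutation(6)
        h2 = hset(bx[perm], by[perm], sy[perm])
        assert ivw(h).beta == pytest.approx(ivw(h2).beta, rel=1e-10)
        assert mr_egger(h).slope.beta == pytest.approx(
            mr_egger(h2).slope.beta, rel=1e-10
        )
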