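import numpy as np
import pytest
import statsmodels.api as sm

from mrshape.exceptions import DomainError, InsufficientInstrumentsError
from mrshape.harmonize import HarmonizedPair
from mrshape.mr_core import (
    egger,
    i2_gx,
    ivw,
    violates_nome,
    wald_ratio,
    weighted_median,
    _weighted_median_point,
)

from conftest import random_pairs


def _pair(bx, by, sx=0.01, sy=0.005, rsid="rs1"):
    return HarmonizedPair(rsid=rsid, effect_allele="A", other_allele="G",
                          beta_x=bx, se_x=sx, beta_y=by, se_y=sy)


def _median_oracle(theta, weights):
    """Cumulative-weight interpolation, written out longhand."""
    order = sorted(range(len(theta)), key=lambda i: theta[i])
    th = [theta[i] for i in order]
    total = sum(weights)
    w = [weights[i] / total for i in order]
    cum, ps = 0.0, []
    for wi in w:
        ps.append(cum + wi / 2.0)
        cum += wi
    if ps[0] >= 0.5:
        return th[0]
    if ps[-1] <= 0.5:
        return th[-1]
    for k in range(1, len(th)):
        if ps[k] >= 0.5:
            return th[k - 1] + (th[k] - th[k - 1]) * (0.5 - ps[k - 1]) / (ps[k] - ps[k - 1])
    raise AssertionError("unreachable")


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(_pair(0.05, 0.10))
        assert est.theta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.005 / 0.05)

    def test_invariant_under_allele_flip(self):
        pair = _pair(0.05, 0.10)
        flipped = pair.flipped()
        assert wald_ratio(flipped).theta == pytest.approx(wald_ratio(pair).theta)
        assert wald_ratio(flipped).se == pytest.approx(wald_ratio(pair).se)

    def test_zero_denominator(self):
        with pytest.raises(DomainError):
            wald_ratio(_pair(0.0, 0.1))

    def test_delta_se_matches_monte_carlo(self):
        # ratio of normals at beta_x = 0.08 (se 0.017): the first-order
        # delta SE should track the simulated ratio spread.  The ratio's
        # raw variance is undefined (normal denominator), so the spread is
        # measured by the central 68.3% quantile range.
        from scipy import stats

        rng = np.random.default_rng(42)
        bx, sx, by, sy = 0.08, 0.017, 0.004, 0.005
        draws = rng.normal(by, sy, 1_000_000) / rng.normal(bx, sx, 1_000_000)
        q_lo, q_hi = np.quantile(draws, [stats.norm.cdf(-1), stats.norm.cdf(1)])
        mc_spread = (q_hi - q_lo) / 2
        est = wald_ratio(_pair(bx, by, sx=sx, sy=sy))
        # reported SE is the outcome-noise term of the delta expansion;
        # with theta near zero it carries essentially the whole variance
        assert est.se == pytest.approx(sy / bx, rel=1e-12)
        assert est.se == pytest.approx(mc_spread, rel=0.05)


class TestIVW:
    def test_single_pair_degrades_to_wald(self):
        pair = _pair(0.05, 0.01)
        with pytest.warns(UserWarning):
            est = ivw([pair], mode="random")
        ref = wald_ratio(pair)
        assert est.theta == pytest.approx(ref.theta) and est.se == pytest.approx(ref.se)

    def test_strict_mode_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw([_pair(0.05, 0.01)], strict=True)

    def test_equal_weight_symmetric_case(self):
        pairs = [_pair(0.05, 0.05, rsid="a"), _pair(0.05, 0.15, rsid="b")]  # ratios 1 and 3
        est = ivw(pairs, mode="fixed")
        assert est.theta == pytest.approx(2.0)
        w = (0.05 / 0.005) ** 2
        assert est.diagnostics["Q"] == pytest.approx(2 * w * 1.0)  # sum w (theta_j - 2)^2

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_wls_through_origin(self, seed):
        rng = np.random.default_rng(seed)
        pairs = random_pairs(rng, 10)
        by = np.array([p.beta_y for p in pairs])
        bx = np.array([p.beta_x for p in pairs])
        w = 1.0 / np.array([p.se_y for p in pairs]) ** 2
        fit = sm.WLS(by, bx[:, None], weights=w).fit()
        for mode in ("fixed", "random"):
            assert ivw(pairs, mode=mode).theta == pytest.approx(fit.params[0], abs=1e-10)

    def test_fixed_and_random_estimates_coincide(self, make_pairs):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pairs = make_pairs(rng, 8)
            fixed = ivw(pairs, mode="fixed")
            random_ = ivw(pairs, mode="random")
            assert fixed.theta == random_.theta
            q = fixed.diagnostics["Q"]
            if q <= len(pairs) - 1:
                assert fixed.se == random_.se
            else:
                assert random_.se > fixed.se

    def test_estimate_within_ratio_range(self, make_pairs):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pairs = make_pairs(rng, 6)
            ratios = [p.beta_y / p.beta_x for p in pairs]
            est = ivw(pairs, mode="fixed")
            assert min(ratios) - 1e-12 <= est.theta <= max(ratios) + 1e-12

    def test_sign_flip_invariance(self, make_pairs):
        rng = np.random.default_rng(3)
        pairs = make_pairs(rng, 10)
        flipped = [p.flipped() if i % 3 == 0 else p for i, p in enumerate(pairs)]
        assert ivw(flipped).theta == pytest.approx(ivw(pairs).theta, abs=1e-14)


class TestWeightedMedian:
    def test_equal_weight_odd_count(self):
        pairs = [_pair(0.05, 0.05 * t, rsid=f"r{t}") for t in (1, 2, 9)]
        est = weighted_median(pairs, n_boot=100, seed=0)
        assert est.theta == pytest.approx(2.0)

    def test_requires_three_pairs_and_seed(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median([_pair(0.05, 0.01)] * 2, seed=0)
        with pytest.raises(ValueError):
            weighted_median([_pair(0.05, 0.01, rsid=f"r{i}") for i in range(3)])

    def test_same_seed_gives_identical_se(self, make_pairs):
        rng = np.random.default_rng(4)
        pairs = make_pairs(rng, 8)
        a = weighted_median(pairs, n_boot=200, seed=99)
        b = weighted_median(pairs, n_boot=200, seed=99)
        assert a.se == b.se and a.theta == b.theta

    def test_majority_valid_weight_keeps_estimate_near_truth(self):
        # 60% of the weight sits on the true ratio 2; shifting the minority
        # by +10 moves the interpolated median far less than the shift
        theta = np.array([1.0, 2.0, 12.0])
        w = np.array([0.2, 0.6, 0.2])
        baseline = _weighted_median_point(theta, w)
        shifted = _weighted_median_point(theta + np.array([10.0, 0.0, 10.0]), w)
        assert baseline == pytest.approx(_median_oracle(list(theta), list(w)))
        assert abs(shifted - 2.0) < 5.0 < 10.0  # bounded, not dragged by the shift

    @pytest.mark.parametrize("n_snps", [3, 4, 5, 6, 7])
    def test_matches_bruteforce_interpolation(self, n_snps):
        rng = np.random.default_rng(n_snps)
        for _ in range(50):
            theta = rng.normal(0.0, 1.0, n_snps)
            w = rng.uniform(0.1, 2.0, n_snps)
            assert _weighted_median_point(theta, w) == pytest.approx(
                _median_oracle(list(theta), list(w)), abs=1e-12
            )

    def test_breakdown_ordering_vs_ivw(self):
        # 40% of instruments carry large directional pleiotropy (planted on
        # the exposure-increasing allele): the median's bias stays bounded
        # while IVW absorbs the planted shift
        rng = np.random.default_rng(10)
        wm_bias, ivw_bias = [], []
        for _ in range(100):
            pairs = random_pairs(rng, 10, theta=0.05)
            bad = set(rng.choice(10, 4, replace=False))
            pairs = [
                _pair(p.beta_x,
                      p.beta_y + (0.05 * np.sign(p.beta_x) if i in bad else 0.0),
                      sx=p.se_x, sy=p.se_y, rsid=p.rsid)
                for i, p in enumerate(pairs)
            ]
            wm_bias.append(weighted_median(pairs, n_boot=10, seed=1).theta - 0.05)
            ivw_bias.append(ivw(pairs, mode="fixed").theta - 0.05)
        assert abs(np.mean(wm_bias)) < abs(np.mean(ivw_bias))


class TestEgger:
    def test_exact_affine_relation_recovered(self):
        bx = [0.04, 0.06, 0.08, 0.1]
        pairs = [_pair(x, 0.02 + 0.5 * x, rsid=f"r{i}") for i, x in enumerate(bx)]
        slope, intercept = egger(pairs)
        assert slope.theta == pytest.approx(0.5, abs=1e-12)
        assert intercept.theta == pytest.approx(0.02, abs=1e-12)

    def test_orientation_invariance(self, make_pairs):
        rng = np.random.default_rng(5)
        pairs = make_pairs(rng, 10)
        flipped = [p.flipped() if i % 2 else p for i, p in enumerate(pairs)]
        s1, i1 = egger(pairs)
        s2, i2 = egger(flipped)
        assert s1.theta == pytest.approx(s2.theta, abs=1e-14)
        assert i1.theta == pytest.approx(i2.theta, abs=1e-14)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_wls_solve(self, seed):
        rng = np.random.default_rng(seed)
        pairs = random_pairs(rng, 20)
        bx = np.array([p.beta_x for p in pairs])
        by = np.array([p.beta_y for p in pairs])
        sy = np.array([p.se_y for p in pairs])
        flip = np.where(bx < 0, -1.0, 1.0)
        fit = sm.WLS(by * flip, sm.add_constant(bx * flip), weights=1.0 / sy**2).fit()
        slope, intercept = egger(pairs)
        assert slope.theta == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.theta == pytest.approx(fit.params[0], abs=1e-10)
        if fit.scale >= 1.0:  # dispersion not floored: SEs must agree too
            assert slope.se == pytest.approx(fit.bse[1], rel=1e-8)
            assert intercept.se == pytest.approx(fit.bse[0], rel=1e-8)

    def test_requires_three_pairs(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger([_pair(0.05, 0.01), _pair(0.06, 0.01)])


class TestI2GX:
    def test_identical_exposure_effects_give_zero(self):
        pairs = [_pair(0.05, 0.01, rsid=f"r{i}") for i in range(5)]
        value = i2_gx(pairs)
        assert value == 0.0 and violates_nome(value)

    def test_large_spread_approaches_one(self):
        pairs = [_pair(0.01 * (i + 1), 0.01, sx=1e-5, rsid=f"r{i}") for i in range(10)]
        assert i2_gx(pairs) > 0.999

    def test_matches_direct_summation(self, make_pairs):
        rng = np.random.default_rng(6)
        pairs = make_pairs(rng, 12)
        bx = np.abs([p.beta_x for p in pairs])
        w = 1.0 / np.array([p.se_x for p in pairs]) ** 2
        mean = np.sum(w * bx) / np.sum(w)
        q = np.sum(w * (bx - mean) ** 2)
        expected = max(0.0, (q - (len(pairs) - 1)) / q)
        assert i2_gx(pairs) == pytest.approx(expected, abs=1e-10)
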