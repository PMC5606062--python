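import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrkit.estimators import (IVW, MREgger, WeightedMedian, WeightedMode,
                              compare_estimates, egger, ivw, to_odds_ratio,
                              weighted_median, weighted_mode)
from mrkit.exceptions import ConfigurationError, InsufficientInstrumentsError

from conftest import hset


def random_instance(rng, n=None):
    n = n or int(rng.integers(3, 30))
    bx = rng.uniform(0.02, 0.41, n)
    by = rng.normal(0.1 * bx, 0.05)
    sy = rng.uniform(0.01, 0.2, n)
    sx = rng.uniform(0.001, 0.01, n)
    return bx, by, sy, sx


class TestIVW:
    def test_closed_form_example(self):
        inst = hset([1.0, 1.0], [0.1, 0.3], [0.1, 0.1])
        fixed = ivw(inst, model="fixed")
        assert fixed.beta == pytest.approx(0.2)
        assert fixed.se == pytest.approx(math.sqrt(1 / 200), abs=1e-6)
        assert fixed.cochran_q == pytest.approx(2.0)
        mre = ivw(inst, model="multiplicative_random_effects")
        assert mre.beta == pytest.approx(0.2)
        assert mre.se == pytest.approx(0.1)

    def test_single_snp_pair_reduces_to_wald_ratio(self):
        # two identical SNPs: the IVW estimate equals the common Wald ratio
        inst = hset([0.5, 0.5], [0.05, 0.05], [0.01, 0.01])
        assert ivw(inst, model="fixed").beta == pytest.approx(0.1)

    def test_all_zero_outcomes(self):
        res = ivw(hset([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], [0.01, 0.01, 0.01]))
        assert res.beta == 0.0 and res.cochran_q == 0.0

    def test_matches_wls_oracle_and_mre_floor(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            bx, by, sy, _ = random_instance(rng)
            fit = sm.WLS(by, bx, weights=sy**-2.0).fit()
            res = ivw(hset(bx, by, sy), model="fixed")
            assert res.beta == pytest.approx(fit.params[0], abs=1e-10)
            mre = ivw(hset(bx, by, sy), model="multiplicative_random_effects")
            assert mre.se >= res.se - 1e-15  # floor at the fixed-effect SE

    def test_q_pvalue_is_chi2_tail(self):
        res = ivw(hset([1.0, 1.0], [0.1, 0.3], [0.1, 0.1]))
        assert res.q_pvalue == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(hset([1.0], [0.1], [0.1]))


class TestEgger:
    def test_exact_interpolation(self):
        inst = hset([1.0, 2.0, 2.0], [0.5, 0.8, 0.8], [0.1, 0.1, 0.1])
        res = egger(inst)
        assert res.beta == pytest.approx(0.3)
        assert res.egger_intercept == pytest.approx(0.2)

    def test_matches_wls_with_intercept_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            bx, by, sy, _ = random_instance(rng)
            fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2.0).fit()
            res = egger(hset(bx, by, sy))
            assert res.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert res.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_zero_intercept_constraint_reproduces_fixed_ivw(self):
        # centring trick: WLS through the origin is IVW; verify Egger's slope
        # approaches it when the data are generated with zero intercept and
        # exactly equals the through-origin WLS oracle
        rng = np.random.default_rng(1)
        bx, by, sy, _ = random_instance(rng, n=12)
        origin = sm.WLS(by, bx, weights=sy**-2.0).fit()
        assert ivw(hset(bx, by, sy), model="fixed").beta == pytest.approx(
            origin.params[0], abs=1e-12)

    def test_collinear_exposure_raises(self):
        with pytest.raises(ConfigurationError, match="zero variance"):
            egger(hset([0.2, 0.2, 0.2], [0.1, 0.2, 0.3], [0.1, 0.1, 0.1]))

    def test_requires_three(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(hset([0.1, 0.2], [0.01, 0.02], [0.1, 0.1]))


class TestWeightedMedian:
    def test_equal_weight_odd_is_sample_median(self):
        res = weighted_median(hset([1, 1, 1], [0.1, 0.2, 0.6], [1, 1, 1]),
                              n_boot=50, seed=0)
        assert res.beta == pytest.approx(0.2)

    def test_equal_weight_even_interpolates_midpoint(self):
        est = WeightedMedian._estimate(np.ones(4), np.array([0.1, 0.3, 0.1, 0.3]),
                                       np.ones(4))
        assert est == pytest.approx(0.2)

    def test_equal_weights_match_numpy_median(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ratios = rng.normal(0, 1, int(rng.integers(3, 15)) * 2 + 1)  # odd n
            est = WeightedMedian._estimate(np.ones_like(ratios), ratios,
                                           np.ones_like(ratios))
            assert est == pytest.approx(np.median(ratios), abs=1e-12)

    def test_robust_to_minority_pleiotropy(self):
        # 40% of instruments pleiotropic but valid ones hold >50% of the
        # inverse-variance weight: the median stays near the truth
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.1, 0.4, 20)
        by = 0.1 * bx
        invalid = np.argsort(bx)[:8]  # lowest-weight 40%
        by[invalid] += 0.05
        sy = np.full(20, 0.002)
        med = weighted_median(hset(bx, by, sy), n_boot=200, seed=1)
        ivw_res = ivw(hset(bx, by, sy))
        assert abs(med.beta - 0.1) < abs(ivw_res.beta - 0.1)
        assert med.beta == pytest.approx(0.1, abs=0.01)


class TestWeightedMode:
    def test_point_mass_returns_it(self):
        for phi in (0.5, 1.0, 2.0):
            res = weighted_mode(hset([1, 1, 1], [0.15, 0.15, 0.15], [1, 1, 1]),
                                phi=phi, n_boot=20, seed=0)
            assert res.beta == pytest.approx(0.15)

    def test_majority_cluster_wins(self):
        ratios = np.array([0.1, 0.11, 0.09, 0.1, 0.5, 0.51])
        est = WeightedMode._estimate(np.ones(6), ratios, np.ones(6), phi=1.0)
        assert est == pytest.approx(0.1, abs=0.03)

    def test_grid_density_matches_bruteforce_argmax(self):
        rng = np.random.default_rng(2)
        theta = rng.normal(0.2, 0.05, 9)
        w = np.ones(9) / 9
        est = WeightedMode._estimate(np.ones(9), theta, np.ones(9), phi=1.0)
        # brute-force oracle on a 20x denser grid
        mu = float(np.sum(w * theta))
        sd = math.sqrt(np.sum(w * (theta - mu) ** 2))
        mad = np.median(np.abs(theta - np.median(theta))) * 1.4826
        h = 0.9 * min(sd, mad) * 9 ** (-0.2)
        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512 * 20)
        dens = np.sum(w * np.exp(-0.5 * ((grid[:, None] - theta) / h) ** 2), axis=1)
        assert est == pytest.approx(grid[np.argmax(dens)], abs=4 * h / 512)

    def test_symmetric_bimodal_tie_returns_lower_mode(self):
        ratios = np.array([0.1, 0.1, 0.5, 0.5])
        est = WeightedMode._estimate(np.ones(4), ratios, np.ones(4), phi=0.3)
        assert est < 0.3

    def test_phi_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            weighted_mode(hset([1, 1, 1], [0.1, 0.2, 0.3], [1, 1, 1]), phi=0.0)


class TestScalingAndReproducibility:
    def test_exposure_scaling_inverts_estimate(self):
        rng = np.random.default_rng(3)
        bx, by, sy, sx = random_instance(rng, n=15)
        c = 2.5
        for fn, kw in [(ivw, {}), (egger, {}),
                       (weighted_median, dict(n_boot=100, seed=4)),
                       (weighted_mode, dict(n_boot=100, seed=4))]:
            base = fn(hset(bx, by, sy, sx), **kw).beta
            scaled = fn(hset(c * bx, by, sy, c * sx), **kw).beta
            assert scaled == pytest.approx(base / c, rel=1e-9)

    def test_outcome_scaling_scales_estimate(self):
        rng = np.random.default_rng(4)
        bx, by, sy, sx = random_instance(rng, n=15)
        c = 3.0
        for fn, kw in [(ivw, {}), (egger, {}),
                       (weighted_median, dict(n_boot=100, seed=4)),
                       (weighted_mode, dict(n_boot=100, seed=4))]:
            base = fn(hset(bx, by, sy, sx), **kw).beta
            scaled = fn(hset(bx, c * by, c * sy, sx), **kw).beta
            assert scaled == pytest.approx(c * base, rel=1e-9)

    def test_bootstrap_bit_reproducible(self):
        rng = np.random.default_rng(6)
        bx, by, sy, sx = random_instance(rng, n=10)
        a = weighted_median(hset(bx, by, sy, sx), n_boot=150, seed=99)
        b = weighted_median(hset(bx, by, sy, sx), n_boot=150, seed=99)
        assert (a.beta, a.se) == (b.beta, b.se)
        c = weighted_mode(hset(bx, by, sy, sx), n_boot=150, seed=99)
        d = weighted_mode(hset(bx, by, sy, sx), n_boot=150, seed=99)
        assert (c.beta, c.se) == (d.beta, d.se)


class TestPresentation:
    def test_or_identity_at_zero(self):
        assert to_odds_ratio(0.0, 0.1)[0] == pytest.approx(1.0)

    def test_or_headline_shape(self):
        or_, lo, hi = to_odds_ratio(0.0770, 0.0283)
        assert (round(or_, 2), round(lo, 2), round(hi, 2)) == (1.08, 1.02, 1.14)

    def test_or_monotone_in_beta(self):
        ors = [to_odds_ratio(b, 0.05)[0] for b in (-0.1, 0.0, 0.1, 0.2)]
        assert ors == sorted(ors)

    def test_compare_equal_estimates(self):
        z, p = compare_estimates(0.1, 0.05, 0.1, 0.03)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_compare_normal_cdf_example(self):
        z, p = compare_estimates(0.1, 0.03, 0.0, 0.04)
        assert z == pytest.approx(2.0)
        assert p == pytest.approx(2 * stats.norm.sf(2.0), abs=1e-10)
        assert p == pytest.approx(0.0455, abs=5e-4)

    def test_compare_antisymmetric(self):
        z1, p1 = compare_estimates(0.2, 0.05, -0.1, 0.07)
        z2, p2 = compare_estimates(-0.1, 0.07, 0.2, 0.05)
        assert z1 == -z2 and p1 == p2
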