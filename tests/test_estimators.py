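import numpy as np
import pytest
import statsmodels.api as sm

from mrsuite.estimators import (
    wald_ratio,
    ivw,
    egger,
    weighted_median,
    raps,
    to_or_scale,
)
from mrsuite.synth import MrSimConfig, simulate_mr_summary
from mrsuite.harmonize import harmonize

from conftest import make_harmonized


def random_set(rng, n=15, theta=0.2, noise=True):
    gamma = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    se_exp = rng.uniform(0.01, 0.03, n)
    se_out = rng.uniform(0.01, 0.03, n)
    big = theta * gamma
    bexp = rng.normal(gamma, se_exp) if noise else gamma
    bout = rng.normal(big, se_out) if noise else big
    return make_harmonized(bexp, se_exp, bout, se_out)


class TestWaldRatio:
    def test_direct_formula(self):
        e = wald_ratio(0.1, 0.02, 0.2, 0.05)
        assert e.theta == pytest.approx(2.0)
        assert e.se == pytest.approx(0.5)

    def test_null_outcome_gives_p_one(self):
        e = wald_ratio(0.1, 0.02, 0.0, 0.05)
        assert e.theta == 0.0
        assert e.pvalue == pytest.approx(1.0)

    def test_sign_cancellation(self):
        a = wald_ratio(0.1, 0.02, 0.2, 0.05)
        b = wald_ratio(-0.1, 0.02, -0.2, 0.05)
        assert a.theta == pytest.approx(b.theta)

    def test_zero_gamma_fatal(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.02, 0.2, 0.05)


class TestIvw:
    def test_needs_two_variants(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(ValueError):
            ivw(h)

    def test_two_identical_variants_equal_wald_ratio(self):
        h = make_harmonized([0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.02, 0.02])
        assert ivw(h).theta == pytest.approx(0.5)

    def test_noiseless_proportional_data_exact(self, rng):
        h = random_set(rng, theta=0.5, noise=False)
        e = ivw(h)
        assert e.theta == pytest.approx(0.5, abs=1e-12)
        assert e.extra["Q"] == pytest.approx(0.0, abs=1e-18)

    def test_matches_wls_oracle(self, rng):
        """Origin-constrained WLS via statsmodels is the independent oracle."""
        for _ in range(20):
            h = random_set(rng)
            fit = sm.WLS(h.beta_out, h.beta_exp[:, None],
                         weights=1.0 / h.se_out**2).fit()
            e = ivw(h, mode="fixed")
            assert e.theta == pytest.approx(fit.params[0], abs=1e-10)
            # statsmodels scales by residual MSE; undo for the FE se
            se_fe = fit.bse[0] / np.sqrt(fit.mse_resid)
            assert e.se == pytest.approx(se_fe, abs=1e-10)

    def test_mre_se_never_below_fixed(self, rng):
        for _ in range(10):
            h = random_set(rng)
            assert ivw(h).se >= ivw(h, mode="fixed").se - 1e-15

    def test_simulation_recovery_within_3se(self):
        exp, out, truth = simulate_mr_summary(
            MrSimConfig(n_snp=50, theta=0.3, seed=123)
        )
        h = harmonize(exp, out)
        e = ivw(h)
        assert abs(e.theta - 0.3) < 3 * e.se

    def test_invariance_to_order_and_joint_sign_flip(self, rng):
        h = random_set(rng)
        perm = rng.permutation(len(h))
        h2 = h.subset(perm)
        sign = rng.choice([-1.0, 1.0], len(h))
        h3 = make_harmonized(sign * h.beta_exp, h.se_exp,
                             sign * h.beta_out, h.se_out)
        assert ivw(h).theta == pytest.approx(ivw(h2).theta, abs=1e-12)
        assert ivw(h).theta == pytest.approx(ivw(h3).theta, abs=1e-12)


class TestEgger:
    def test_exact_affine_fit(self):
        h = make_harmonized([1.0, 2.0, 3.0], [0.1] * 3,
                            [0.6, 1.1, 1.6], [0.1] * 3)
        est, intercept = egger(h)
        assert est.theta == pytest.approx(0.5, abs=1e-12)
        assert intercept.intercept == pytest.approx(0.1, abs=1e-12)

    def test_matches_wls_oracle_on_oriented_data(self, rng):
        for _ in range(20):
            h = random_set(rng)
            sign = np.where(h.beta_exp < 0, -1.0, 1.0)
            X = sm.add_constant(sign * h.beta_exp)
            fit = sm.WLS(sign * h.beta_out, X, weights=1.0 / h.se_out**2).fit()
            est, intercept = egger(h)
            assert est.theta == pytest.approx(fit.params[1], abs=1e-10)
            assert intercept.intercept == pytest.approx(fit.params[0], abs=1e-10)

    def test_directional_pleiotropy_less_biased_than_ivw(self):
        """Shifted-mean direct effects with InSIDE holding: Egger's slope
        stays near the truth while IVW absorbs the intercept as bias."""
        theta = 0.2
        egger_err, ivw_err = [], []
        for seed in range(40):
            exp, out, _ = simulate_mr_summary(MrSimConfig(
                n_snp=100, theta=theta, pleiotropy_mode="directional",
                pleiotropy_scale=0.1, seed=seed))
            h = harmonize(exp, out)
            est, _ = egger(h)
            egger_err.append(est.theta - theta)
            ivw_err.append(ivw(h).theta - theta)
        assert abs(np.mean(egger_err)) < abs(np.mean(ivw_err))
        assert abs(np.mean(ivw_err)) > 0.05  # IVW really is biased here

    def test_needs_three_variants(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(ValueError):
            egger(h)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.1] * 3,
                            [1.0, 2.0, 3.0], [0.5] * 3)
        e = weighted_median(h, n_boot=100, seed=1)
        assert e.theta == pytest.approx(2.0)

    def test_breakdown_resistance(self):
        h = make_harmonized([1.0] * 4, [0.1] * 4,
                            [1.0, 2.0, 3.0, 100.0], [0.5] * 4)
        e = weighted_median(h, n_boot=100, seed=1)
        assert 2.0 <= e.theta <= 3.0

    def test_seed_mandatory(self, random_harmonized):
        with pytest.raises(ValueError):
            weighted_median(random_harmonized, n_boot=100, seed=None)

    def test_deterministic_given_seed(self, random_harmonized):
        a = weighted_median(random_harmonized, n_boot=200, seed=9)
        b = weighted_median(random_harmonized, n_boot=200, seed=9)
        assert (a.theta, a.se) == (b.theta, b.se)

    def test_contaminated_simulation_recovery(self):
        """40% of weight pleiotropic: the weighted median still recovers."""
        rng = np.random.default_rng(77)
        n = 30
        gamma = rng.uniform(0.1, 0.3, n)
        se = np.full(n, 0.02)
        big = 0.4 * gamma
        big[:12] += 0.15  # invalid minority
        h = make_harmonized(gamma, np.full(n, 0.01),
                            rng.normal(big, se), se)
        e = weighted_median(h, n_boot=500, seed=5)
        assert abs(e.theta - 0.4) < 3 * e.se


class TestRaps:
    def test_noiseless_proportional_data(self, rng):
        h = random_set(rng, theta=0.5, noise=False)
        e = raps(h, overdispersion=False)
        assert e.theta == pytest.approx(0.5, abs=1e-6)

    def test_zero_exposure_noise_limit_equals_ivw(self, rng):
        h = random_set(rng)
        h2 = make_harmonized(h.beta_exp, np.full(len(h), 1e-10),
                             h.beta_out, h.se_out)
        e = raps(h2, overdispersion=False)
        assert e.theta == pytest.approx(ivw(h2, mode="fixed").theta, abs=1e-6)

    def test_weak_instruments_less_biased_than_ivw(self):
        """Many weak instruments: profile-score correction beats IVW."""
        theta = 0.1
        raps_err, ivw_err = [], []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            n = 200
            gamma = rng.normal(0, 0.03, n)
            se_exp = np.full(n, 0.01)  # mean F ~ 10-15
            se_out = np.full(n, 0.01)
            h = make_harmonized(rng.normal(gamma, se_exp), se_exp,
                                rng.normal(theta * gamma, se_out), se_out)
            raps_err.append(raps(h).theta - theta)
            ivw_err.append(ivw(h).theta - theta)
        assert abs(np.mean(raps_err)) < abs(np.mean(ivw_err))

    def test_huber_loss_tolerates_one_outlier(self, rng):
        h = random_set(rng, n=30, theta=0.3)
        bout = h.beta_out.copy()
        bout[0] += 1.0  # gross idiosyncratic outlier
        hc = make_harmonized(h.beta_exp, h.se_exp, bout, h.se_out)
        rob = raps(hc, loss="huber")
        sq = raps(hc, loss="squared")
        assert abs(rob.theta - 0.3) < abs(sq.theta - 0.3)


class TestOrScale:
    def test_null_maps_to_unit_or(self, random_harmonized):
        e = ivw(random_harmonized)
        e.theta, e.ci_low, e.ci_high = 0.0, -0.1, 0.1
        assert to_or_scale(e).or_scale[0] == pytest.approx(1.0)

    def test_three_decimal_convention(self):
        e = ivw(make_harmonized([1.0, 1.0], [0.1] * 2, [-0.003, -0.003],
                                [0.001] * 2))
        e.theta, e.ci_low, e.ci_high = -0.003, -0.005, -0.001
        orv, lo, hi = to_or_scale(e).or_scale
        assert (round(orv, 3), round(lo, 3), round(hi, 3)) == (0.997, 0.995, 0.999)

    def test_monotone_in_theta(self):
        h = make_harmonized([1.0, 1.0], [0.1] * 2, [0.2, 0.2], [0.1] * 2)
        small, large = ivw(h), ivw(h)
        small.theta, large.theta = 0.1, 0.5
        assert to_or_scale(small).or_scale[0] < to_or_scale(large).or_scale[0]
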