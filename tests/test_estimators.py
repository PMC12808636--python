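"""MR estimators: exact identities, independent oracles, robustness sims."""
import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from pwmr.errors import EstimationError
from pwmr.estimators import (IVW, EggerRegression, WaldRatio, WeightedMedian,
                             WeightedMode, bh_fdr, ivw, wald_ratio,
                             _weighted_linear_fit)
from pwmr.sumstats import HarmonizedPair


def _pair(beta_x=2.0, se_x=0.1, beta_y=1.0, se_y=0.2, rsid="rs1"):
    return HarmonizedPair(rsid, "A", beta_x, se_x, 0.3, beta_y, se_y, 0.3,
                          "aligned")


class TestWaldRatio:
    def test_first_order_formula(self):
        est = wald_ratio(_pair())
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.ci_low == pytest.approx(0.5 - 1.959964 * 0.1, abs=1e-6)

    def test_null_numerator_gives_p_one(self):
        est = wald_ratio(_pair(beta_y=0.0))
        assert est.beta == 0.0 and est.pval == 1.0

    def test_zero_exposure_beta_raises_with_rsid(self):
        with pytest.raises(EstimationError, match="rsX"):
            wald_ratio(_pair(beta_x=0.0, rsid="rsX"))

    def test_second_order_se_value(self):
        est = wald_ratio(_pair(), se_order="second")
        assert est.se == pytest.approx(0.10308, abs=5e-6)

    def test_second_order_se_against_monte_carlo_delta(self):
        """The delta-method SE matches the sampled sd of the ratio within 3%."""
        rng = np.random.default_rng(0)
        bx = rng.normal(2.0, 0.1, 1_000_000)
        by = rng.normal(1.0, 0.2, 1_000_000)
        mc_sd = np.std(by / bx)
        est = wald_ratio(_pair(), se_order="second")
        assert est.se == pytest.approx(mc_sd, rel=0.03)


class TestIVW:
    def test_single_snp_equals_wald_bitwise(self):
        p = _pair()
        w = wald_ratio(p)
        hz_est = IVW().fit([p.beta_x], [p.beta_y], se_y=[p.se_y])
        assert hz_est.beta_ == w.beta
        assert hz_est.se_ == w.se
        assert hz_est.pval_ == w.pval
        assert hz_est.model_ == "fixed"

    def test_two_identical_snps_closed_form(self):
        est = IVW().fit([1.0, 1.0], [0.5, 0.5], se_y=[0.1, 0.1])
        assert est.beta_ == pytest.approx(0.5)
        assert est.se_ == pytest.approx(0.1 / np.sqrt(2), abs=1e-12)

    def test_against_statsmodels_wls(self, rng):
        bx = rng.uniform(0.05, 0.2, 8)
        by = 0.4 * bx + rng.normal(0, 0.02, 8)
        sy = rng.uniform(0.01, 0.05, 8)
        fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
        est = IVW(model="fixed").fit(bx, by, se_y=sy)
        assert est.beta_ == pytest.approx(fit.params[0], rel=1e-10)

    def test_random_effects_never_deflate(self, rng):
        bx = rng.uniform(0.05, 0.2, 10)
        sy = np.full(10, 0.001)
        by = 0.4 * bx + rng.normal(0, 0.05, 10)  # strong heterogeneity
        fixed = IVW(model="fixed").fit(bx, by, se_y=sy)
        random = IVW(model="random").fit(bx, by, se_y=sy)
        assert random.se_ >= fixed.se_

    def test_sixteen_snp_recovery(self, rng):
        """Estimate covers the true effect 0.24 in >=93/100 replicates."""
        hits = 0
        for _ in range(100):
            bx_t = rng.uniform(0.05, 0.15, 16)
            se_x = bx_t / 30  # F = 900
            se_y = np.full(16, 0.01)
            bx = rng.normal(bx_t, se_x)
            by = rng.normal(0.24 * bx_t, se_y)
            est = IVW().fit(bx, by, se_y=se_y)
            hits += est.ci_low_ <= 0.24 <= est.ci_high_
        assert hits >= 93


class TestEgger:
    def test_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        est = EggerRegression().fit(bx, 0.3 * bx, se_y=np.full(4, 0.05))
        assert est.intercept_ == pytest.approx(0.0, abs=1e-12)
        assert est.beta_ == pytest.approx(0.3, abs=1e-12)

    def test_exact_affine_interpolation(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = EggerRegression().fit(bx, 0.05 + 0.3 * bx, se_y=np.full(3, 0.05))
        assert est.intercept_ == pytest.approx(0.05, abs=1e-12)
        assert est.beta_ == pytest.approx(0.3, abs=1e-12)

    def test_against_statsmodels_wls(self, rng):
        bx = rng.uniform(0.05, 0.2, 12)
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.02, 12)
        sy = rng.uniform(0.01, 0.05, 12)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        est = EggerRegression().fit(bx, by, se_y=sy)
        assert est.intercept_ == pytest.approx(fit.params[0], rel=1e-9)
        assert est.beta_ == pytest.approx(fit.params[1], rel=1e-9)

    def test_minimum_instruments_enforced(self):
        with pytest.raises(EstimationError, match="3"):
            EggerRegression().fit([0.1, 0.2], [0.1, 0.2], se_y=[0.1, 0.1])

    def test_directional_pleiotropy_detected(self):
        """A +0.05 direct outcome effect on every SNP shows up in the intercept
        in >=80% of 200 replicates at 50 instruments."""
        rng = np.random.default_rng(3)
        detected = 0
        for _ in range(200):
            bx = rng.uniform(0.05, 0.15, 50)
            sy = np.full(50, 0.03)
            by = 0.3 * bx + 0.05 + rng.normal(0, sy)
            est = EggerRegression().fit(bx, by, se_y=sy)
            detected += est.intercept_pval_ < 0.05
        assert detected >= 160

    def test_zero_intercept_fit_equals_ivw(self, rng):
        """The shared WLS routine constrained through the origin is IVW."""
        for _ in range(20):
            k = rng.integers(3, 12)
            bx = rng.uniform(0.05, 0.3, k)
            by = 0.3 * bx + rng.normal(0, 0.03, k)
            sy = rng.uniform(0.01, 0.06, k)
            w = 1 / sy**2
            constrained = _weighted_linear_fit(bx, by, w, intercept=False)
            est = IVW(model="fixed").fit(bx, by, se_y=sy)
            assert constrained["coef"][0] == pytest.approx(est.beta_, rel=1e-12)
            assert constrained["se_fixed"][0] == pytest.approx(est.se_, rel=1e-12)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        est = WeightedMedian(n_boot=10).fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0],
                                            se_y=[0.1, 0.1, 0.1])
        assert est.beta_ == pytest.approx(2.0)

    def test_degenerate_ratios(self):
        est = WeightedMedian(n_boot=200, seed=1).fit(
            [1.0, 1.0, 1.0], [0.7, 0.7, 0.7], se_y=[1e-8, 1e-8, 1e-8])
        assert est.beta_ == pytest.approx(0.7)
        assert est.se_ < 1e-6

    def test_robust_to_half_invalid_instruments(self):
        """With 50% of instruments carrying large balanced pleiotropic
        offsets, the weighted median lands closer to the truth than IVW in
        >=90% of replicates."""
        rng = np.random.default_rng(5)
        closer = 0
        for _ in range(200):
            bx = rng.uniform(0.08, 0.12, 10)
            sy = np.full(10, 0.005)
            by = 0.3 * bx + rng.normal(0, sy)
            by[:5] += rng.uniform(0.1, 0.3, 5) * rng.choice([-1.0, 1.0], 5)
            wm = WeightedMedian(n_boot=50, seed=1).fit(bx, by, se_y=sy)
            iv = IVW().fit(bx, by, se_y=sy)
            closer += abs(wm.beta_ - 0.3) < abs(iv.beta_ - 0.3)
        assert closer >= 180


class TestWeightedMode:
    def test_all_ratios_equal(self):
        est = WeightedMode(n_boot=10).fit([1.0, 1.0, 1.0], [0.4, 0.4, 0.4],
                                          se_y=[1e-9, 1e-9, 1e-9])
        assert est.beta_ == pytest.approx(0.4)

    def test_plurality_mode_wins(self):
        bx = np.ones(10)
        by = np.array([0.3] * 7 + [1.0] * 3) + np.linspace(-0.002, 0.002, 10)
        est = WeightedMode(n_boot=10).fit(bx, by, se_y=np.full(10, 0.05))
        assert est.beta_ == pytest.approx(0.3, abs=0.05)

    def test_order_invariance(self, rng):
        bx = rng.uniform(0.05, 0.2, 12)
        by = 0.3 * bx + rng.normal(0, 0.01, 12)
        sy = rng.uniform(0.01, 0.03, 12)
        a = WeightedMode(n_boot=10, seed=1).fit(bx, by, se_y=sy)
        perm = rng.permutation(12)
        b = WeightedMode(n_boot=10, seed=1).fit(bx[perm], by[perm], se_y=sy[perm])
        assert a.beta_ == pytest.approx(b.beta_, abs=1e-12)


@pytest.mark.parametrize("cls,kw", [
    (IVW, {}), (EggerRegression, {}),
    (WeightedMedian, {"n_boot": 20, "seed": 2}),
    (WeightedMode, {"n_boot": 20, "seed": 2}),
])
def test_joint_sign_flip_equivariance(cls, kw, rng):
    bx = rng.uniform(0.05, 0.2, 8)
    by = 0.3 * bx + rng.normal(0, 0.02, 8)
    sy = rng.uniform(0.01, 0.05, 8)
    a = cls(**kw).fit(bx, by, se_y=sy)
    b = cls(**kw).fit(-bx, -by, se_y=sy)
    assert a.beta_ == pytest.approx(b.beta_, rel=1e-9)


class TestBHFDR:
    def test_single_test(self):
        adj, rej = bh_fdr([0.04])
        assert adj[0] == pytest.approx(0.04) and rej[0]

    def test_stepup_all_rejected(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert rej.all()
        assert adj[-1] == pytest.approx(0.04)

    def test_empty(self):
        adj, rej = bh_fdr([])
        assert adj.size == 0 and rej.size == 0

    def test_against_brute_force_oracle(self, rng):
        """min-over-tail definition: adj_(i) = min_{j>=i} min(1, m p_(j)/j)."""
        for _ in range(100):
            m = int(rng.integers(1, 30))
            p = rng.uniform(1e-6, 1, m)
            adj, _ = bh_fdr(p)
            order = np.argsort(p)
            expected = np.empty(m)
            sorted_p = p[order]
            for i in range(m):
                expected[i] = min(min(1.0, m * sorted_p[j] / (j + 1))
                                  for j in range(i, m))
            np.testing.assert_allclose(adj[order], expected, rtol=1e-12)


@given(st.floats(0.01, 0.99))
def test_bh_rejection_consistent_with_adjusted_p(q):
    p = [0.001, 0.02, 0.2, 0.9]
    adj, rej = bh_fdr(p, q=q)
    np.testing.assert_array_equal(rej, adj <= q)
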