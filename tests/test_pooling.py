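"""Rubin's-rules pooling: hand oracles, complements, degenerate cases."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from hwimpute import (DomainError, GenotypeCounts, clamp_pvalue, estimate_f,
                      exact_test, pool_estimates, pool_exact_pvalues,
                      pool_z_statistics, signed_z, transform_pvalue)
from hwimpute.pooling import EPS_MIN, EPS_ONE

from conftest import random_polymorphic_counts


class TestClampAndTransform:
    def test_clamp_endpoints_and_interior(self):
        assert clamp_pvalue(0.0) == EPS_MIN
        assert clamp_pvalue(1.0) == 1.0 - EPS_ONE
        assert clamp_pvalue(0.3) == 0.3

    def test_clamp_rejects_outside_unit_interval(self):
        with pytest.raises(DomainError):
            clamp_pvalue(-0.1)
        with pytest.raises(DomainError):
            clamp_pvalue(1.1)

    def test_transform_values(self):
        assert transform_pvalue(0.5) == pytest.approx(0.0, abs=1e-15)
        assert transform_pvalue(0.025) == pytest.approx(1.95996, abs=1e-5)
        z0 = transform_pvalue(0.0)
        assert math.isfinite(z0) and z0 > 30  # clamped, large positive
        z1 = transform_pvalue(1.0)
        assert math.isfinite(z1) and z1 < -5


class TestPoolEstimates:
    def test_identical_estimates_normal_limit(self):
        r = pool_estimates([(0.1, 0.01)] * 7)
        assert r.B == 0.0 and r.T == pytest.approx(0.01)
        assert math.isinf(r.nu)
        assert r.Q == pytest.approx(1.0)
        assert r.p_mi == pytest.approx(2 * norm.sf(1.0), abs=1e-10)

    def test_hand_oracle_m2(self):
        r = pool_estimates([(0.0, 0.01), (0.2, 0.01)])
        assert r.estimate == pytest.approx(0.1)
        assert r.W == pytest.approx(0.01)
        assert r.B == pytest.approx(0.02, abs=1e-15)
        assert r.T == pytest.approx(0.04, abs=1e-15)
        assert r.nu == pytest.approx((1 + (2 * 0.01) / (3 * 0.02)) ** 2, abs=1e-4)

    def test_total_variance_decomposition(self, rng):
        for _ in range(50):
            m = int(rng.integers(2, 12))
            f = rng.normal(size=m)
            v = rng.uniform(0.5, 2.0, size=m)
            r = pool_estimates(list(zip(f, v)))
            if r.B > 0:
                assert r.T == pytest.approx(r.W + (1 + 1 / m) * r.B, abs=1e-12)
            assert r.T >= r.W - 1e-15
            assert r.ci_low <= r.estimate <= r.ci_high

    def test_single_imputation_rejected(self):
        with pytest.raises(DomainError, match="single-imputation"):
            pool_estimates([(0.1, 0.01)])


class TestPoolZ:
    def test_all_zero(self):
        assert pool_z_statistics([0.0, 0.0, 0.0]).p_mi == pytest.approx(1.0)

    def test_hand_oracle_m2(self):
        r = pool_z_statistics([1.0, 3.0])
        assert r.estimate == pytest.approx(2.0)
        assert r.W == 1.0
        assert r.B == pytest.approx(2.0)
        assert r.T == pytest.approx(1 + 1.5 * 2)

    def test_equivalent_to_f_pooling_with_null_variance(self, rng):
        # z_i = sqrt(n) f_i makes chi2-pooling and f-pooling the same test
        n = 120
        for _ in range(30):
            counts = []
            while len(counts) < 5:
                c = rng.multinomial(n, [0.25, 0.5, 0.25])
                gc = GenotypeCounts(*(int(v) for v in c))
                if not gc.is_monomorphic:
                    counts.append(gc)
            rf = pool_estimates([(estimate_f(c).f_hat, 1.0 / n) for c in counts])
            rz = pool_z_statistics([signed_z(c) for c in counts])
            assert rz.Q == pytest.approx(rf.Q, abs=1e-10)
            assert rz.p_mi == pytest.approx(rf.p_mi, abs=1e-10)


class TestPoolExactPvalues:
    def test_uniform_center(self):
        r = pool_exact_pvalues([0.5, 0.5, 0.5])
        assert r.z_bar == 0.0 and r.B == 0.0
        assert r.p_mi_deficiency == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("c", [0.01, 0.2, 0.77])
    def test_constant_pvalues_round_trip(self, c):
        # B = 0, T = 1, normal limit: the pooled p returns the input
        r = pool_exact_pvalues([c] * 5)
        assert r.p_mi_deficiency == pytest.approx(c, abs=1e-10)

    def test_hand_oracle_m2_chain(self):
        r = pool_exact_pvalues([0.025, 0.5])
        z = [norm.isf(0.025), 0.0]
        z_bar = np.mean(z)
        B = float(np.var(z, ddof=1))
        T = 1 + 1.5 * B
        nu = (1 + 2 * 1.0 / (3 * B)) ** 2
        assert r.z_bar == pytest.approx(z_bar, abs=1e-4)
        assert r.B == pytest.approx(B, abs=1e-4)
        assert r.T == pytest.approx(T, abs=1e-4)
        assert r.nu == pytest.approx(nu, rel=1e-4)
        from scipy.stats import t as t_dist
        assert r.p_mi_deficiency == pytest.approx(
            float(t_dist.sf(z_bar / math.sqrt(T), nu)), abs=1e-10)

    def test_complement_carry_over(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 10))
            p = rng.uniform(0.001, 0.999, size=m)
            r = pool_exact_pvalues(list(p))
            rc = pool_exact_pvalues(list(1.0 - p))
            assert rc.p_mi_deficiency == pytest.approx(1.0 - r.p_mi_deficiency, abs=1e-10)
            assert r.p_mi_excess == 1.0 - r.p_mi_deficiency  # bit-exact by construction
            assert r.p_mi_two_sided <= 1.0

    def test_monotone_in_pvalues_at_fixed_B(self):
        # on the B = 0 family, smaller p_i means smaller pooled deficiency p
        pooled = [pool_exact_pvalues([c] * 4).p_mi_deficiency
                  for c in (0.4, 0.3, 0.2, 0.1, 0.05)]
        assert all(a > b for a, b in zip(pooled, pooled[1:]))

    def test_extreme_pvalues_stay_finite(self):
        r = pool_exact_pvalues([0.0, 1e-300, 0.0])
        assert 0.0 <= r.p_mi_deficiency < 1e-6
        r = pool_exact_pvalues([1.0, 1.0])
        assert r.p_mi_deficiency > 1 - 1e-6


class TestEndToEndCalibration:
    def test_mi_exact_test_holds_level_under_mcar(self):
        # f = 0 markers with 10% MCAR, marginal imputation (m = 10):
        # pooled two-sided rejection stays near the nominal 5% level
        from hwimpute import MarkerDataset, impute_with_fallback
        from hwimpute.counts import MISSING

        rng = np.random.default_rng(77)
        probs = [0.09, 0.42, 0.49]  # HWE at p_A = 0.3
        rejections, reps = 0, 2000
        for i in range(reps):
            g = rng.choice(3, size=100, p=probs).astype(np.int8)
            mask = rng.random(100) < 0.10
            g[mask] = MISSING
            if len(np.unique(g[g != MISSING])) < 2:
                continue
            ds = MarkerDataset(f"h{i}", g)
            imp = impute_with_fallback(ds, m=10, seed=int(rng.integers(2 ** 31)))
            pooled = pool_exact_pvalues(
                [exact_test(c).p_deficiency_mid for c in imp.counts])
            rejections += pooled.p_mi_two_sided < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestZeroMissingEquivalence:
    def test_pooled_equals_complete_data_p(self, rng):
        # identical imputations: every pooled p equals the complete-data p
        for _ in range(20):
            c = random_polymorphic_counts(rng)
            ex = exact_test(c)
            r = pool_exact_pvalues([ex.p_deficiency_mid] * 10)
            assert r.p_mi_deficiency == pytest.approx(ex.p_deficiency_mid, abs=1e-10)
            assert r.p_mi_excess == pytest.approx(ex.p_excess_mid, abs=1e-10)
            assert r.p_mi_two_sided == pytest.approx(
                2 * min(ex.p_deficiency_mid, ex.p_excess_mid), abs=1e-10)
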