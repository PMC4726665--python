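"""Fisher combination, SMD pooling, heterogeneity gating and BH FDR."""

import numpy as np
import pytest
from scipy import integrate, stats as sps

from metamodule.meta import (
    bh_fdr,
    fisher_combine,
    fisher_combine_matrix,
    heterogeneity,
    pool_effect,
    smd_per_study,
)


class TestFisher:
    def test_all_ones_give_zero_statistic(self):
        stat, p = fisher_combine([1.0] * 6)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_against_quadrature_oracle(self):
        # six p-values of 0.05: statistic = 12 ln 20; tail from direct
        # numerical integration of the chi2_12 density
        stat, p = fisher_combine([0.05] * 6)
        assert stat == pytest.approx(12 * np.log(20))
        oracle, _ = integrate.quad(lambda x: sps.chi2.pdf(x, 12), stat, np.inf)
        assert p == pytest.approx(oracle, rel=1e-8)

    def test_rejects_zero_and_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])
        with pytest.raises(ValueError):
            fisher_combine([])

    def test_uniform_null_combined_p_is_uniform(self, rng):
        P = rng.uniform(size=(4000, 5))
        _, p = fisher_combine_matrix(P)
        assert sps.kstest(p, "uniform").statistic < 0.03


class TestSmd:
    def test_hand_computed_hedges_g(self):
        # n=20/20, mean diff 1, pooled SD 2 -> d=0.5, J=1-3/151
        g, var = smd_per_study(20, 20, 1.0, 0.0, 2.0, 2.0)
        assert g == pytest.approx(0.5 * (1 - 3 / 151), abs=1e-6)

    def test_equal_means_variance(self):
        g, var = smd_per_study(10, 15, 1.0, 1.0, 0.8, 0.8)
        j = 1 - 3 / (4 * 23 - 1)
        assert g == 0.0
        assert var == pytest.approx((25 / 150) * j**2)

    def test_sign_flips_when_groups_swap(self):
        g1, _ = smd_per_study(12, 9, 2.0, 1.0, 0.7, 0.9)
        g2, _ = smd_per_study(9, 12, 1.0, 2.0, 0.9, 0.7)
        assert g1 == pytest.approx(-g2)

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError):
            smd_per_study(5, 5, 1.0, 0.0, 0.0, 0.0)


class TestHeterogeneity:
    def test_identical_effects_give_zero(self):
        q, i2 = heterogeneity([0.3, 0.3, 0.3], [0.1, 0.1, 0.1])
        assert q == pytest.approx(0.0)
        assert i2 == 0.0

    def test_hand_computed_q_and_i2(self):
        q, i2 = heterogeneity([0.5, -0.5], [0.1, 0.1])
        assert q == pytest.approx(5.0)
        assert i2 == pytest.approx(80.0)

    def test_null_q_follows_chi2(self, rng):
        k, n_rep = 5, 4000
        v = np.full(k, 0.04)
        qs = []
        for _ in range(n_rep):
            g = rng.normal(0.2, np.sqrt(v))
            q, _ = heterogeneity(g, v)
            qs.append(q)
        emp = np.percentile(qs, 95)
        assert emp == pytest.approx(sps.chi2.ppf(0.95, k - 1), rel=0.08)

    def test_requires_positive_variances(self):
        with pytest.raises(ValueError):
            heterogeneity([0.1, 0.2], [0.1, 0.0])


class TestPooling:
    def test_fixed_effects_hand_example(self):
        model, pooled, se, z, es_p = pool_effect([0.4, 0.6], [0.04, 0.04])
        assert model == "fixed"
        assert pooled == pytest.approx(0.5)
        assert se == pytest.approx(np.sqrt(0.02))
        assert z == pytest.approx(0.5 / np.sqrt(0.02))

    def test_zero_q_collapses_random_onto_fixed(self):
        g, v = [0.5, 0.5, 0.5], [0.09, 0.09, 0.09]
        _, pooled_f, se_f, _, _ = pool_effect(g, v)
        # force the random model via the same inputs: tau2 = 0 when Q = 0
        q, i2 = heterogeneity(g, v)
        assert q == pytest.approx(0.0)
        w = 1 / np.asarray(v)
        assert pooled_f == pytest.approx(np.sum(w * g) / np.sum(w))
        assert se_f == pytest.approx(1 / np.sqrt(np.sum(w)))

    def test_model_gate_matches_both_conditions(self):
        # strong heterogeneity -> Q-test p < 0.05 and I2 > 50 -> random
        model, *_ = pool_effect([1.5, -1.5, 1.5], [0.02, 0.02, 0.02])
        assert model == "random"
        model, *_ = pool_effect([0.50, 0.52, 0.48], [0.04, 0.04, 0.04])
        assert model == "fixed"

    def test_random_effects_se_not_below_fixed(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 8))
            g = rng.normal(0, 1, size=k)
            v = rng.uniform(0.01, 0.2, size=k)
            q, i2 = heterogeneity(g, v)
            w = 1 / v
            se_fixed = 1 / np.sqrt(w.sum())
            denom = w.sum() - (w**2).sum() / w.sum()
            tau2 = max(0.0, (q - (k - 1)) / denom)
            se_random = 1 / np.sqrt((1 / (v + tau2)).sum())
            assert se_random >= se_fixed - 1e-12

    def test_pooled_smd_recovers_generating_value(self, rng):
        # k=6 homogeneous studies, n=40/40, 500 genes: |bias| < 0.05
        k, n, n_genes, true_g = 6, 40, 500, 0.5
        est = np.empty((n_genes, k))
        var = np.empty_like(est)
        for j in range(k):
            hi = rng.normal(true_g, 1, size=(n_genes, n))
            lo = rng.normal(0.0, 1, size=(n_genes, n))
            g, v = smd_per_study(n, n, hi.mean(1), lo.mean(1),
                                 hi.std(1, ddof=1), lo.std(1, ddof=1))
            est[:, j], var[:, j] = g, v
        pooled = np.array([pool_effect(est[i], var[i])[1] for i in range(n_genes)])
        assert abs(pooled.mean() - true_g) < 0.05


class TestBhFdr:
    def test_single_p_passes_through(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_are_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
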