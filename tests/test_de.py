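import numpy as np
import pandas as pd
import pytest
import scipy.stats

import gczoner as gz
from gczoner.de import EBPrior, deg_summary, estimate_prior, fit_groupwise, moderated_t


def _dataset(X, n_a, n_b):
    X = np.asarray(X, dtype=float)
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    expr = pd.DataFrame(X, index=[f"G{i:03d}" for i in range(X.shape[0])], columns=samples)
    meta = pd.DataFrame(
        {"sample_id": samples, "group": ["A"] * n_a + ["B"] * n_b,
         "batch": "b1", "run_type": "paired"}
    )
    return expr, meta


class TestFitGroupwise:
    def test_hand_pooled_variance(self):
        expr, meta = _dataset([[2.0, 4.0, 1.0, 3.0]], 2, 2)
        fit = fit_groupwise(expr, meta, ("A", "B"))
        row = fit.iloc[0]
        assert row.logFC == pytest.approx(1.0)
        assert row.s2 == pytest.approx(2.0)
        assert row.df == 2.0
        assert row.v == pytest.approx(1.0)

    def test_identical_means_zero_logfc(self):
        expr, meta = _dataset([[3.0, 5.0, 4.0, 4.0]], 2, 2)
        assert fit_groupwise(expr, meta, ("A", "B")).iloc[0].logFC == pytest.approx(0.0)

    def test_within_group_permutation_invariant(self, rng):
        X = rng.normal(0, 1, (20, 8))
        expr, meta = _dataset(X, 4, 4)
        f1 = fit_groupwise(expr, meta, ("A", "B"))
        shuffled = expr[["A2", "A0", "A3", "A1", "B1", "B3", "B0", "B2"]]
        f2 = fit_groupwise(shuffled, meta, ("A", "B"))
        pd.testing.assert_frame_equal(f1.drop(columns="ave_expr"), f2.drop(columns="ave_expr"))

    def test_small_group_rejected(self):
        expr, meta = _dataset([[1.0, 2.0, 3.0]], 1, 2)
        with pytest.raises(ValueError, match=">= 2 samples"):
            fit_groupwise(expr, meta, ("A", "B"))


class TestEstimatePrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = estimate_prior(np.full(50, 0.7), df=4.0)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.7, rel=1e-6)

    def test_recovers_known_hyperparameters(self):
        # s_g^2 = s0^2 * F(df, d0) with d0 = 4, s0^2 = 0.25
        rng = np.random.default_rng(2024)
        s2 = 0.25 * rng.f(4, 4, size=5000)
        prior = estimate_prior(s2, df=4.0)
        assert prior.d0 == pytest.approx(4.0, rel=0.25)
        assert prior.s0_sq == pytest.approx(0.25, rel=0.10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        s2 = 0.5 * rng.f(4, 6, size=2000)
        p1 = estimate_prior(s2, df=4.0)
        p2 = estimate_prior(2.0 * s2, df=4.0)
        assert p2.s0_sq == pytest.approx(2.0 * p1.s0_sq, rel=1e-9)
        assert p2.d0 == pytest.approx(p1.d0, rel=1e-9)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            estimate_prior(np.ones(5), df=4.0)


class TestModeratedT:
    def test_hand_shrinkage_computation(self):
        expr, meta = _dataset([[2.0, 4.0, 1.0, 3.0]], 2, 2)
        fit = fit_groupwise(expr, meta, ("A", "B"))
        res = moderated_t(fit, EBPrior(d0=4.0, s0_sq=1.0))
        # s~^2 = (4*1 + 2*2)/6 = 4/3; t = 1/sqrt(4/3 * 1); df = 6
        s2_post = 4.0 / 3.0
        t_exp = 1.0 / np.sqrt(s2_post)
        assert res.iloc[0].s2_post == pytest.approx(s2_post)
        assert res.iloc[0].t == pytest.approx(t_exp)
        assert res.iloc[0].p == pytest.approx(2 * scipy.stats.t.sf(t_exp, 6))

    def test_zero_prior_df_is_ordinary_t(self, rng):
        X = rng.normal(0, 1, (30, 10))
        expr, meta = _dataset(X, 5, 5)
        fit = fit_groupwise(expr, meta, ("A", "B"))
        res = moderated_t(fit, EBPrior(d0=0.0, s0_sq=1.0))
        t_ref, p_ref = scipy.stats.ttest_ind(X[:, :5].T, X[:, 5:].T, equal_var=True)
        assert np.allclose(res["t"], t_ref, atol=1e-10)
        assert np.allclose(res["p"], p_ref, atol=1e-10)

    def test_infinite_prior_df_pins_variance(self, rng):
        X = rng.normal(0, 1, (10, 8))
        expr, meta = _dataset(X, 4, 4)
        fit = fit_groupwise(expr, meta, ("A", "B"))
        res = moderated_t(fit, EBPrior(d0=np.inf, s0_sq=0.42))
        assert np.allclose(res["s2_post"], 0.42)

    def test_posterior_variance_between_prior_and_sample(self, rng):
        X = rng.normal(0, 1.5, (50, 8))
        expr, meta = _dataset(X, 4, 4)
        fit = fit_groupwise(expr, meta, ("A", "B"))
        prior = EBPrior(d0=3.0, s0_sq=1.0)
        res = moderated_t(fit, prior)
        lo = np.minimum(prior.s0_sq, fit["s2"])
        hi = np.maximum(prior.s0_sq, fit["s2"])
        inner = fit["s2"] != prior.s0_sq
        assert ((res["s2_post"] > lo - 1e-12) & (res["s2_post"] < hi + 1e-12))[inner].all()

    def test_threshold_test_is_conservative(self, rng):
        X = rng.normal(0, 1, (100, 8)) + rng.normal(0, 1, (100, 1))
        expr, meta = _dataset(X, 4, 4)
        fit = fit_groupwise(expr, meta, ("A", "B"))
        prior = estimate_prior(fit["s2"], 6.0)
        p0 = moderated_t(fit, prior, lfc_threshold=0.0)["p"]
        p1 = moderated_t(fit, prior, lfc_threshold=0.8)["p"]
        assert (p1 >= p0 - 1e-12).all()

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(77)
        X = rng.normal(0, 1, (1000, 10))
        expr, meta = _dataset(X, 5, 5)
        fit = fit_groupwise(expr, meta, ("A", "B"))
        res = moderated_t(fit)
        ks = scipy.stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01


class TestAgainstLimma:
    """Reference values computed with limma (lmFit/eBayes/treat) on the
    same deterministically generated matrices."""

    def _fix2(self):
        rng = np.random.default_rng(7)
        sd = rng.uniform(0.3, 3.0, 60)
        X = np.round(
            rng.normal(5, 1, (60, 6)) * 0 + 5 + rng.normal(0, 1, (60, 6)) * sd[:, None],
            6,
        )
        X[:5, :3] += 2.0
        return _dataset(X, 3, 3)

    def test_finite_prior_matches_limma(self):
        expr, meta = self._fix2()
        fit = fit_groupwise(expr, meta, ("A", "B"))
        prior = estimate_prior(fit["s2"], 4.0)
        assert prior.d0 == pytest.approx(2.66705976, rel=1e-6)
        assert prior.s0_sq == pytest.approx(1.131240363, rel=1e-6)
        res = moderated_t(fit, prior)
        expected_t = {"G000": 0.7143243971, "G003": 2.42973899,
                      "G010": -1.0766764, "G025": 0.6681767144,
                      "G059": -3.910636272}
        expected_p = {"G000": 0.4992643443, "G003": 0.04714555672,
                      "G010": 0.3190342156, "G025": 0.5264669148,
                      "G059": 0.006405357977}
        for g in expected_t:
            assert res.loc[g, "t"] == pytest.approx(expected_t[g], rel=1e-6)
            assert res.loc[g, "p"] == pytest.approx(expected_p[g], rel=1e-6)

    def test_infinite_prior_matches_limma(self):
        rng = np.random.default_rng(42)
        X = np.round(rng.normal(5, 1, (50, 6)), 6)
        X[:5, :3] += 1.5
        expr, meta = _dataset(X, 3, 3)
        fit = fit_groupwise(expr, meta, ("A", "B"))
        prior = estimate_prior(fit["s2"], 4.0)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.7920465098, rel=1e-6)
        res = moderated_t(fit, prior)
        assert res.loc["G000", "t"] == pytest.approx(3.132073799, rel=1e-6)
        # p differs only by the df convention in the d0 = inf limit: here
        # the t reference uses d0 + d_g df (normal limit); limma caps df
        # at the pooled residual df (200) instead
        assert res.loc["G000", "p"] == pytest.approx(0.001996149067, rel=0.15)
        assert res.loc["G049", "p"] == pytest.approx(0.3513820228, rel=0.02)

    def test_threshold_test_matches_limma_treat(self):
        expr, meta = self._fix2()
        fit = fit_groupwise(expr, meta, ("A", "B"))
        prior = estimate_prior(fit["s2"], 4.0)
        res = moderated_t(fit, prior, lfc_threshold=0.5)
        expected = {"G000": 0.5264174554, "G003": 0.06590560058,
                    "G010": 0.4062898795, "G025": 0.5465357626,
                    "G059": 0.008032823887}
        for g, p in expected.items():
            assert res.loc[g, "p"] == pytest.approx(p, rel=1e-6)


class TestDegSummary:
    def test_no_significant_genes(self, rng):
        X = rng.normal(0, 1, (50, 8))
        expr, meta = _dataset(X, 4, 4)
        res = moderated_t(fit_groupwise(expr, meta, ("A", "B")), lfc_threshold=2.0)
        assert deg_summary(res) == (0, 0, 0)

    def test_negating_contrast_swaps_up_and_down(self, rng):
        X = rng.normal(0, 0.4, (120, 12))
        X[:25, :6] += 3.0
        X[25:60, 6:] += 3.0
        expr, meta = _dataset(X, 6, 6)
        res_ab = moderated_t(fit_groupwise(expr, meta, ("A", "B")), lfc_threshold=1.0)
        res_ba = moderated_t(fit_groupwise(expr, meta, ("B", "A")), lfc_threshold=1.0)
        tot_ab, up_ab, down_ab = deg_summary(res_ab)
        tot_ba, up_ba, down_ba = deg_summary(res_ba)
        assert (tot_ab, up_ab, down_ab) == (tot_ba, down_ba, up_ba)

    def test_planted_counts_recovered(self):
        rng = np.random.default_rng(31)
        X = rng.normal(5, 0.5, (500, 16))
        X[:40, :8] += 3.0     # 40 genes up in A
        X[40:100, 8:] += 3.0  # 60 genes up in B = down in A-vs-B
        expr, meta = _dataset(X, 8, 8)
        res = moderated_t(fit_groupwise(expr, meta, ("A", "B")), lfc_threshold=1.0)
        n_total, n_up, n_down = deg_summary(res)
        assert 36 <= n_up <= 42
        assert 55 <= n_down <= 62
        assert n_total == n_up + n_down
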