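"""cis-eQTL machinery: OLS against an independent oracle, adaptive
permutations with the Beta extrapolation, eGene calling and stepwise
conditional analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tests.conftest import toy_genotypes
from tissueqtl import synthetic as syn
from tissueqtl.cis import (
    call_egenes,
    cis_window_variants,
    empirical_p_cut,
    gene_nominal_threshold,
    nominal_scan,
    permutation_pass,
    significant_pairs,
    stepwise_conditional,
)
from tissueqtl.regression import beta_mle, ols_scan


def ols_oracle(y, g, covariates=None):
    """Hand-rolled full-design OLS for one variant (lstsq + classic SEs)."""
    n = len(y)
    x = [np.ones(n), g]
    if covariates is not None:
        x.extend(list(covariates.T))
    x = np.column_stack(x)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    df = n - x.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(x.T @ x)
    beta, se = coef[1], np.sqrt(cov[1, 1])
    t = beta / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta, se, t, p


class TestNominalScan:
    def test_matches_ols_oracle_simple(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        y = np.array([0.1, 1.0, 2.1, -0.1, 1.1, 1.9])
        res = ols_scan(y, g[:, None])
        b, se, t, p = ols_oracle(y, g)
        assert abs(res.beta[0] - b) < 1e-8
        assert abs(res.se[0] - se) < 1e-8
        assert abs(res.t[0] - t) < 1e-8
        assert abs(res.p[0] - p) < 1e-8

    def test_matches_ols_oracle_with_covariates(self):
        rng = np.random.default_rng(1)
        n = 80
        g = rng.integers(0, 3, n).astype(float)
        c = rng.normal(size=(n, 4))
        y = 0.3 * g + c @ rng.normal(size=4) + rng.normal(size=n)
        res = ols_scan(y, g[:, None], covariates=c)
        b, se, t, p = ols_oracle(y, g, c)
        np.testing.assert_allclose(
            [res.beta[0], res.se[0], res.t[0], res.p[0]], [b, se, t, p],
            atol=1e-8,
        )

    def test_noiseless_fit(self):
        g = np.array([0.0, 1, 2, 0, 1, 2, 0, 1, 2])
        res = ols_scan(2.0 * g, g[:, None])
        assert abs(res.beta[0] - 2.0) < 1e-10
        assert res.p[0] < 1e-12

    def test_t_equals_beta_over_se(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, (60, 5)).astype(float)
        y = rng.normal(size=60)
        res = ols_scan(y, g)
        np.testing.assert_allclose(res.t, res.beta / res.se, atol=1e-10)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        g = rng.integers(0, 3, 50).astype(float)
        for _ in range(1000):
            y = rng.normal(size=50)
            ps.append(ols_scan(y, g[:, None]).p[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCisWindow:
    def test_boundary_and_filters(self):
        rng = np.random.default_rng(4)
        n = 400
        dosage = rng.binomial(2, 0.3, size=(n, 4))
        dosage[:, 1] = 0
        dosage[:5, 1] = 1          # MAF 5/800 = 0.00625 < 0.01 -> excluded
        dosage[:, 2] = 0
        dosage[:12, 2] = 1         # MAF 0.015 but only... 12 carriers -> kept
        dosage[:, 3] = 0
        dosage[:9, 3] = 2          # 9 carrier samples < 10 -> excluded
        gt = toy_genotypes(dosage, spacing=1)
        gt.variants.loc[3, "pos"] = 1_000_005  # exactly TSS + window
        gene = pd.Series({"gene": "g", "chrom": "chr1", "tss": 5})
        idx = cis_window_variants(
            gene, gt, np.arange(n), window=1_000_000
        )
        kept = set(gt.variants["variant"].to_numpy()[idx])
        assert "v0" in kept
        assert "v1" not in kept      # tissue MAF below 0.01
        assert "v2" in kept
        assert "v3" not in kept      # minor allele in < 10 samples
        # boundary inclusion: give v3 frequency and carriers, stays at edge
        dosage[:, 3] = rng.binomial(2, 0.4, size=n)
        gt2 = toy_genotypes(dosage, spacing=1)
        gt2.variants.loc[3, "pos"] = 1_000_005
        idx2 = cis_window_variants(gene, gt2, np.arange(n), window=1_000_000)
        assert 3 in idx2

    def test_missing_chromosome_empty(self):
        gt = toy_genotypes(np.random.default_rng(5).binomial(2, 0.3, (20, 2)))
        gene = pd.Series({"gene": "g", "chrom": "chrX", "tss": 100})
        assert cis_window_variants(gene, gt, np.arange(20)).size == 0


class TestPermutationPass:
    def test_single_variant_minima_uniform_beta_fit(self):
        # min of one uniform p is uniform: fitted Beta(k,n) near (1,1)
        rng = np.random.default_rng(6)
        n = 200
        dosage = rng.binomial(2, 0.4, size=(n, 1))
        gt = toy_genotypes(dosage)
        y = rng.normal(size=n)
        res, _ = permutation_pass(
            "g", np.array([0]), y, gt, np.arange(n), None, "T0",
            n_min=10_000, n_max=10_000, seed=7,
        )
        assert abs(res.beta_k - 1.0) < 0.1
        assert abs(res.beta_n - 1.0) < 0.1

    def test_orthogonal_variants_beta_n_near_m(self):
        # minima of M independent uniforms ~ Beta(1, M)
        rng = np.random.default_rng(8)
        n, m = 500, 8
        dosage = rng.binomial(2, 0.5, size=(n, m))
        gt = toy_genotypes(dosage)
        y = rng.normal(size=n)
        res, _ = permutation_pass(
            "g", np.arange(m), y, gt, np.arange(n), None, "T0",
            n_min=10_000, n_max=10_000, seed=9,
        )
        assert abs(res.beta_n - m) / m < 0.15
        assert abs(res.beta_k - 1.0) < 0.15

    def test_observed_p_one_maps_to_empirical_one(self):
        assert stats.beta.cdf(1.0, 0.9, 12.0) == 1.0

    def test_adaptive_early_stop_on_null(self):
        rng = np.random.default_rng(10)
        n = 100
        gt = toy_genotypes(rng.binomial(2, 0.4, size=(n, 3)))
        y = rng.normal(size=n)
        res, _ = permutation_pass(
            "g", np.arange(3), y, gt, np.arange(n), None, "T0",
            n_min=500, n_max=10_000, seed=11,
        )
        assert res.n_perm == 500  # null gene: plenty of hits at n_min

    def test_beta_and_direct_p_agree(self):
        rng = np.random.default_rng(12)
        n = 150
        gt = toy_genotypes(rng.binomial(2, 0.3, size=(n, 5)))
        emp, direct = [], []
        for i in range(40):
            y = rng.normal(size=n)
            res, _ = permutation_pass(
                "g", np.arange(5), y, gt, np.arange(n), None, "T0",
                n_min=1_000, n_max=1_000, seed=100 + i,
            )
            emp.append(res.p_empirical)
            direct.append(res.p_direct)
        rho = stats.spearmanr(emp, direct).statistic
        assert rho >= 0.97

    def test_too_few_permutations_refused(self):
        gt = toy_genotypes(np.zeros((20, 1), dtype=int))
        with pytest.raises(ValueError, match="Beta fit"):
            permutation_pass(
                "g", np.array([0]), np.zeros(20), gt, np.arange(20), None,
                "T0", n_min=10, n_max=50,
            )


class TestBetaMle:
    def test_recovers_known_shapes(self):
        rng = np.random.default_rng(13)
        x = rng.beta(1.0, 30.0, size=20_000)
        a, b = beta_mle(x)
        assert abs(a - 1.0) < 0.05
        assert abs(b - 30.0) / 30.0 < 0.05

    def test_uniform_gives_one_one(self):
        rng = np.random.default_rng(14)
        a, b = beta_mle(rng.random(20_000))
        assert abs(a - 1.0) < 0.05 and abs(b - 1.0) < 0.05


class TestEgeneCalling:
    def test_global_null_no_egenes(self):
        res = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(100)],
             "p_empirical": np.ones(100)}
        )
        out = call_egenes(res)
        assert not out["egene"].any()

    def test_planted_mixture_calls(self):
        rng = np.random.default_rng(15)
        n_false = []
        n_true = []
        for s in range(5):
            p = np.concatenate(
                [np.full(10, 1e-8),
                 np.random.default_rng(s).random(990)]
            )
            res = pd.DataFrame(
                {"gene": [f"g{i}" for i in range(1000)], "p_empirical": p}
            )
            out = call_egenes(res, fdr=0.05)
            called = set(out.loc[out["egene"], "gene"])
            n_true.append(len(called & {f"g{i}" for i in range(10)}))
            n_false.append(len(called - {f"g{i}" for i in range(10)}))
        assert np.mean(n_true) >= 9.5
        assert np.mean(n_false) <= 1.0

    def test_single_gene_q_equals_p(self):
        res = pd.DataFrame({"gene": ["g"], "p_empirical": [0.2]})
        out = call_egenes(res)
        assert out["q_value"].iloc[0] == pytest.approx(0.2)

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(16)
        res = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(200)],
             "p_empirical": rng.random(200)}
        )
        out = call_egenes(res).sort_values("p_empirical")
        assert np.all(np.diff(out["q_value"]) >= -1e-12)


class TestNominalThreshold:
    def test_beta_one_one_identity(self):
        assert gene_nominal_threshold(1.0, 1.0, 0.05) == pytest.approx(0.05)

    def test_beta_one_hundred_closed_form(self):
        expected = 1.0 - 0.95 ** (1.0 / 100.0)
        assert gene_nominal_threshold(1.0, 100.0, 0.05) == pytest.approx(
            expected, rel=1e-10
        )

    def test_no_significant_genes_no_thresholds(self):
        res = pd.DataFrame(
            {"gene": ["a", "b"], "p_empirical": [0.5, 0.9],
             "egene": [False, False], "beta_k": [1, 1], "beta_n": [5, 5]}
        )
        assert empirical_p_cut(res) is None
        pairs = pd.DataFrame(
            {"gene": ["a"], "variant": ["v"], "tissue": ["T0"],
             "beta": [0.1], "se": [0.1], "t": [1.0], "p_nominal": [0.3]}
        )
        assert len(significant_pairs(res, pairs)) == 0

    def test_ld_proxies_all_significant(self, small_gt, small_genes):
        # a strong planted eQTL in an LD block: high-r^2 proxies join the
        # significant-pair list
        eff_gene = small_genes.iloc[0]
        block_vars = small_gt.variants[
            small_gt.variants["chrom"] == eff_gene["chrom"]
        ]
        assert len(block_vars) > 0
        vi = int(block_vars.index[0])
        n = small_gt.n_donors
        rng = np.random.default_rng(17)
        y = small_gt.dosage[:, vi] * 1.0 + rng.normal(0, 0.3, n)
        from tissueqtl.preprocess import inverse_normal_transform

        y = inverse_normal_transform(y)
        gene = pd.Series(
            {"gene": "g", "chrom": eff_gene["chrom"],
             "tss": int(small_gt.variants.loc[vi, "pos"])}
        )
        vidx = cis_window_variants(gene, small_gt, np.arange(n))
        res, records = permutation_pass(
            "g", vidx, y, small_gt, np.arange(n), None, "T0",
            n_min=1000, n_max=1000, seed=18,
        )
        thresh = gene_nominal_threshold(res.beta_k, res.beta_n, 0.05)
        sig_vars = set(
            records.loc[records["p_nominal"] <= thresh, "variant"]
        )
        lead = small_gt.dosage[:, vi].astype(float)
        for j in vidx:
            proxy = small_gt.dosage[:, j].astype(float)
            r2 = np.corrcoef(lead, proxy)[0, 1] ** 2
            if r2 >= 0.9:
                assert small_gt.variants.loc[j, "variant"] in sig_vars


class TestStepwise:
    def _setup(self, seed, betas, m=30, n=300):
        rng = np.random.default_rng(seed)
        dosage = rng.binomial(2, 0.4, size=(n, m))
        gt = toy_genotypes(dosage)
        causal = [0, m // 2][: len(betas)]
        y = rng.normal(0, 1.0, n)
        for c, b in zip(causal, betas):
            y = y + b * dosage[:, c]
        from tissueqtl.preprocess import inverse_normal_transform

        return gt, inverse_normal_transform(y), causal

    def test_single_causal_yields_one_signal(self):
        gt, y, causal = self._setup(19, [1.0])
        out = stepwise_conditional(
            "g", np.arange(gt.n_variants), y, gt, np.arange(len(y)), None,
            "T0", p_cut=0.01, seed=20,
        )
        assert len(out) == 1
        found = gt.variant_index(out["variant"].iloc[0])
        r2 = np.corrcoef(
            gt.dosage[:, found].astype(float),
            gt.dosage[:, causal[0]].astype(float),
        )[0, 1] ** 2
        assert found == causal[0] or r2 >= 0.9

    def test_two_independent_causals_found(self):
        gt, y, causal = self._setup(21, [1.0, 1.0])
        out = stepwise_conditional(
            "g", np.arange(gt.n_variants), y, gt, np.arange(len(y)), None,
            "T0", p_cut=0.01, seed=22,
        )
        assert len(out) == 2
        found = {gt.variant_index(v) for v in out["variant"]}
        for c in causal:
            assert any(
                np.corrcoef(
                    gt.dosage[:, f].astype(float),
                    gt.dosage[:, c].astype(float),
                )[0, 1] ** 2 >= 0.9
                for f in found
            )

    def test_null_gene_yields_empty(self):
        rng = np.random.default_rng(23)
        gt = toy_genotypes(rng.binomial(2, 0.4, size=(200, 10)))
        y = rng.normal(size=200)
        out = stepwise_conditional(
            "g", np.arange(10), y, gt, np.arange(200), None, "T0",
            p_cut=0.01, seed=24,
        )
        assert len(out) == 0

    def test_variant_order_insensitive(self):
        gt, y, _ = self._setup(25, [1.2])
        order1 = np.arange(gt.n_variants)
        order2 = order1[::-1].copy()
        a = stepwise_conditional("g", order1, y, gt, np.arange(len(y)),
                                 None, "T0", p_cut=0.01, seed=26)
        b = stepwise_conditional("g", order2, y, gt, np.arange(len(y)),
                                 None, "T0", p_cut=0.01, seed=26)
        assert list(a["variant"]) == list(b["variant"])
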