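"""ASE site filtering, haplotype aggregation, imbalance testing, allelic
fold change, phasing-error model and the distal cis detector."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tissueqtl.ase import (
    AFC_CAP,
    afc_from_ase,
    afc_from_eqtl,
    aggregate_gene_haplotypes,
    binomial_imbalance_test,
    binomial_two_sided_p,
    distal_cis_test,
    filter_ase_sites,
    fit_phasing_error_model,
    monoallelic_test,
    _betabin_logpmf,
)


def _sites(rows):
    df = pd.DataFrame(
        rows,
        columns=["donor", "tissue", "gene", "site", "ref_count",
                 "alt_count", "hap_assignment"],
    )
    for flag in ("low_mappability", "mapping_bias", "genotype_suspect"):
        if flag not in df:
            df[flag] = False
    return df


class TestSiteFilter:
    def test_coverage_boundary(self):
        sites = _sites(
            [("d", "t", "g", "s1", 3, 4, "A"),   # 7 reads -> dropped
             ("d", "t", "g", "s2", 4, 4, "A")]   # 8 reads -> kept
        )
        out = filter_ase_sites(sites)
        assert list(out["site"]) == ["s2"]

    def test_flags_drop_sites(self):
        sites = _sites([("d", "t", "g", "s1", 10, 10, "A"),
                        ("d", "t", "g", "s2", 10, 10, "A")])
        sites.loc[0, "mapping_bias"] = True
        out = filter_ase_sites(sites)
        assert list(out["site"]) == ["s2"]


class TestAggregation:
    def test_two_site_addition(self):
        # site 1 alt on hap A with (alt=5, ref=10); site 2 alt on hap A
        # with (alt=7, ref=3): hapA = 5+7 = 12, hapB = 10+3 = 13
        sites = _sites(
            [("d", "t", "g", "s1", 10, 5, "A"),
             ("d", "t", "g", "s2", 3, 7, "A")]
        )
        agg, n_unphased = aggregate_gene_haplotypes(sites)
        assert n_unphased == 0
        row = agg.iloc[0]
        assert (row["hap_a_count"], row["hap_b_count"]) == (12, 13)
        assert row["n_sites"] == 2

    def test_single_site_passthrough(self):
        sites = _sites([("d", "t", "g", "s1", 6, 9, "B")])
        agg, _ = aggregate_gene_haplotypes(sites)
        assert (agg.iloc[0]["hap_a_count"], agg.iloc[0]["hap_b_count"]) == (6, 9)

    def test_phase_flip_swaps_haplotypes(self):
        sites = _sites(
            [("d", "t", "g", "s1", 10, 5, "A"),
             ("d", "t", "g", "s2", 3, 7, "B")]
        )
        flipped = sites.copy()
        flipped["hap_assignment"] = flipped["hap_assignment"].map(
            {"A": "B", "B": "A"}
        )
        a, _ = aggregate_gene_haplotypes(sites)
        b, _ = aggregate_gene_haplotypes(flipped)
        assert a.iloc[0]["hap_a_count"] == b.iloc[0]["hap_b_count"]
        assert a.iloc[0]["hap_b_count"] == b.iloc[0]["hap_a_count"]

    def test_unphased_sites_excluded_and_counted(self):
        sites = _sites([("d", "t", "g", "s1", 10, 5, "A")])
        sites.loc[1] = ["d", "t", "g", "s2", 3, 7, None,
                        False, False, False]
        agg, n_unphased = aggregate_gene_haplotypes(sites)
        assert n_unphased == 1
        assert agg.iloc[0]["n_sites"] == 1


class TestImbalanceTest:
    def test_perfect_balance_p_one(self):
        counts = pd.DataFrame(
            {"donor": ["d"], "tissue": ["t"], "gene": ["g"],
             "hap_a_count": [4], "hap_b_count": [4], "n_sites": [1]}
        )
        out = binomial_imbalance_test(counts)
        assert out["p_binomial"].iloc[0] == pytest.approx(1.0)
        assert not out["imbalanced"].iloc[0]

    def test_eight_zero_exact_tail(self):
        assert binomial_two_sided_p(np.array([8]), np.array([8]))[0] == (
            pytest.approx(2 * 0.5**8)
        )

    def test_thirty_eighteen_not_called(self):
        counts = pd.DataFrame(
            {"donor": ["d"], "tissue": ["t"], "gene": ["g"],
             "hap_a_count": [30], "hap_b_count": [18], "n_sites": [1]}
        )
        out = binomial_imbalance_test(counts)
        p = out["p_binomial"].iloc[0]
        es = out["effect_size"].iloc[0]
        assert p == pytest.approx(0.112, abs=5e-3)
        assert abs(es) == pytest.approx(np.log2(31 / 19), rel=1e-9)
        assert abs(es) < 1.0
        assert not out["imbalanced"].iloc[0]

    def test_matches_exact_binomial_oracle_all_small_counts(self):
        ks, ns = [], []
        for n in range(1, 51):
            for k in range(n + 1):
                ks.append(k)
                ns.append(n)
        ours = binomial_two_sided_p(np.array(ks), np.array(ns))
        for k, n, p in zip(ks, ns, ours):
            oracle = stats.binomtest(k, n, 0.5).pvalue
            assert abs(p - oracle) < 1e-12

    def test_zero_total_untestable(self):
        counts = pd.DataFrame(
            {"donor": ["d"], "tissue": ["t"], "gene": ["g"],
             "hap_a_count": [0], "hap_b_count": [0], "n_sites": [1]}
        )
        assert len(binomial_imbalance_test(counts)) == 0


class TestAfcFromEqtl:
    def _fit(self, means, reps=30, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        g = np.repeat([0, 1, 2], reps)
        y = np.repeat(means, reps) * np.exp(rng.normal(0, noise, g.size))
        return afc_from_eqtl("g", "v", "t", y, g, n_boot=0)

    def test_class_means_one_and_half_two(self):
        est = self._fit([1.0, 1.5, 2.0])
        assert est.k == pytest.approx(1.0, abs=1e-5)

    def test_flat_means_zero(self):
        est = self._fit([1.7, 1.7, 1.7])
        assert est.k == pytest.approx(0.0, abs=1e-5)

    def test_decreasing_means_negative(self):
        est = self._fit([2.0, 1.5, 1.0])
        assert est.k == pytest.approx(-1.0, abs=1e-5)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            afc_from_eqtl("g", "v", "t", np.ones(10), np.zeros(10))

    def test_cap_applied(self):
        est = self._fit([1.0, 500.0, 1e6])
        assert abs(est.k) <= AFC_CAP + 1e-9


class TestAfcFromAse:
    def test_single_donor_pseudocount_formula(self):
        hc = pd.DataFrame(
            {"hap_a_count": [20], "hap_b_count": [10],
             "evariant_alt_hap": ["A"]}
        )
        est = afc_from_ase("g", "v", "t", hc)
        assert est.k == pytest.approx(np.log2(21 / 11), rel=1e-9)

    def test_balanced_donors_near_zero(self):
        hc = pd.DataFrame(
            {"hap_a_count": [30, 29, 31], "hap_b_count": [30, 31, 29],
             "evariant_alt_hap": ["A", "B", "A"]}
        )
        est = afc_from_ase("g", "v", "t", hc)
        assert abs(est.k) < 0.1

    def test_alt_hap_orientation_respected(self):
        hc = pd.DataFrame(
            {"hap_a_count": [10], "hap_b_count": [40],
             "evariant_alt_hap": ["B"]}
        )
        est = afc_from_ase("g", "v", "t", hc)
        assert est.k == pytest.approx(np.log2(41 / 11), rel=1e-9)

    def test_no_het_donors_rejected(self):
        with pytest.raises(ValueError):
            afc_from_ase("g", "v", "t", pd.DataFrame())


class TestPhasingErrorModel:
    def _training(self, eps_fn, n=4000, seed=70):
        rng = np.random.default_rng(seed)
        dist = 10.0 ** rng.uniform(2, 6, n)
        maf1 = rng.uniform(0.05, 0.5, n)
        maf2 = rng.uniform(0.05, 0.5, n)
        eps = eps_fn(dist, maf1, maf2)
        flipped = rng.random(n) < eps
        return pd.DataFrame(
            {"distance": dist, "maf1": maf1, "maf2": maf2,
             "flipped": flipped}
        )

    def test_constant_error_intercept_only(self):
        tr = self._training(lambda d, m1, m2: np.full(d.size, 0.2))
        model = fit_phasing_error_model(tr)
        preds = model.predict(tr["distance"], tr["maf1"], tr["maf2"])
        assert abs(preds.mean() - 0.2) < 0.03

    def test_monotone_in_distance(self):
        tr = self._training(
            lambda d, m1, m2: np.clip(0.05 + 0.1 * (np.log10(d) - 2), 0, 0.5)
        )
        model = fit_phasing_error_model(tr)
        d_grid = np.logspace(2, 6, 10)
        preds = model.predict(d_grid, np.full(10, 0.3), np.full(10, 0.3))
        assert np.all(np.diff(preds) >= -1e-12)

    def test_auc_with_planted_distance_effect(self):
        from sklearn.metrics import roc_auc_score

        tr = self._training(
            lambda d, m1, m2: np.where(np.log10(d) > 4, 0.45, 0.02),
            n=6000, seed=71,
        )
        test = self._training(
            lambda d, m1, m2: np.where(np.log10(d) > 4, 0.45, 0.02),
            n=3000, seed=72,
        )
        model = fit_phasing_error_model(tr)
        preds = model.predict(test["distance"], test["maf1"], test["maf2"])
        assert roc_auc_score(test["flipped"], preds) >= 0.8

    def test_single_class_rejected(self):
        tr = self._training(lambda d, m1, m2: np.zeros(d.size))
        with pytest.raises(ValueError, match="single-class"):
            fit_phasing_error_model(tr)

    def test_predictions_clipped_to_half(self):
        tr = self._training(lambda d, m1, m2: np.full(d.size, 0.45))
        model = fit_phasing_error_model(tr)
        preds = model.predict([1e12], [0.5], [0.5])
        assert preds[0] <= 0.5


class TestDistalCisTest:
    def _simulate(self, p1, eps, n_het=15, n_hom=15, depth=60, seed=0):
        rng = np.random.default_rng(seed)
        het_total = np.full(n_het, depth)
        flips = rng.random(n_het) < eps
        probs = np.where(flips, 1 - p1, p1)
        het_alt = rng.binomial(depth, probs)
        hom_total = np.full(n_hom, depth)
        hom_hap = rng.binomial(depth, 0.5, n_hom)
        return het_alt, het_total, hom_hap, hom_total

    def test_power_with_planted_imbalance(self):
        het_alt, het_total, hom_hap, hom_total = self._simulate(
            0.75, 0.0, seed=73
        )
        res = distal_cis_test(het_alt, het_total, hom_hap, hom_total, 0.0)
        assert res["p"] < 0.01
        assert abs(res["p1"] - 0.75) < 0.1

    def test_type_one_error_calibrated(self):
        rejections = 0
        n_sims = 400
        for s in range(n_sims):
            het_alt, het_total, hom_hap, hom_total = self._simulate(
                0.5, 0.0, seed=1000 + s
            )
            res = distal_cis_test(het_alt, het_total, hom_hap, hom_total,
                                  0.0)
            rejections += res["p"] < 0.05
        rate = rejections / n_sims
        assert 0.02 <= rate <= 0.09

    def test_worst_case_phasing_error_degrades_power(self):
        # at 50% phasing error the haplotype orientation is pure noise;
        # only the unsigned bimodality of heterozygote imbalance remains,
        # so power drops sharply at moderate effects (though the mixture
        # test keeps some sensitivity for strong imbalances)
        def rate(eps):
            rej = 0
            n_sims = 100
            for s in range(n_sims):
                het_alt, het_total, hom_hap, hom_total = self._simulate(
                    0.6, eps, depth=20, seed=5000 + s
                )
                res = distal_cis_test(
                    het_alt, het_total, hom_hap, hom_total, eps
                )
                rej += res["p"] < 0.05
            return rej / n_sims

        assert rate(0.0) >= 0.8
        assert rate(0.5) <= 0.35

    def test_epsilon_zero_reduces_to_pure_betabinomial(self):
        het_alt = np.array([40.0, 42, 38])
        het_total = np.array([60.0, 60, 60])
        l1 = _betabin_logpmf(het_alt, het_total, 0.7, 0.05)
        eps = np.zeros(3)
        mx = np.maximum(l1, _betabin_logpmf(het_alt, het_total, 0.3, 0.05))
        mix = mx + np.log(
            (1 - eps) * np.exp(l1 - mx)
            + eps * np.exp(
                _betabin_logpmf(het_alt, het_total, 0.3, 0.05) - mx
            )
        )
        np.testing.assert_allclose(mix, l1, atol=1e-10)

    def test_no_hets_untestable(self):
        with pytest.raises(ValueError):
            distal_cis_test([], [], [30], [60])


class TestMonoallelicCheck:
    def test_tiny_minor_fraction_supports_monoallelic(self):
        assert monoallelic_test(0, 100) > 0.3

    def test_substantial_minor_fraction_rejects(self):
        assert monoallelic_test(30, 100) < 1e-10
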