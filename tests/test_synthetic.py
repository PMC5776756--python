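"""Generator contracts: determinism, MAF control, LD structure, planted
effects showing through with the promised magnitudes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tissueqtl import synthetic as syn
from tissueqtl.datatypes import SyntheticTruth


class TestGenotypes:
    def test_same_seed_identical(self):
        a = syn.simulate_genotypes(50, 40, (0.1, 0.5), 4, seed=1)
        b = syn.simulate_genotypes(50, 40, (0.1, 0.5), 4, seed=1)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_hard_calls_and_unique_positions(self, small_gt):
        small_gt.validate()
        assert set(np.unique(small_gt.dosage)) <= {0, 1, 2}

    def test_block_size_one_uncorrelated(self):
        gt = syn.simulate_genotypes(500, 60, (0.2, 0.5), 1, seed=2)
        r = np.corrcoef(gt.dosage.T.astype(float))
        off = np.abs(r[np.triu_indices(60, k=1)])
        # independent sampling: pairwise |r| concentrated near 0
        assert np.quantile(off, 0.95) < 0.1
        assert off.mean() < 0.05

    def test_within_block_correlated(self, small_gt):
        d = small_gt.dosage.astype(float)
        r = abs(np.corrcoef(d[:, 0], d[:, 1])[0, 1])  # same block of 5
        assert r > 0.5

    def test_requested_maf_honored(self):
        gt = syn.simulate_genotypes(10_000, 30, (0.3, 0.3), 5, seed=3)
        maf = gt.empirical_maf()
        assert maf.min() >= 0.27 and maf.max() <= 0.33

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            syn.simulate_genotypes(1, 10, (0.1, 0.5), 5, seed=0)
        with pytest.raises(ValueError):
            syn.simulate_genotypes(10, 0, (0.1, 0.5), 5, seed=0)
        with pytest.raises(ValueError):
            syn.simulate_genotypes(10, 10, (0.0, 0.6), 5, seed=0)


class TestExpression:
    def test_additive_afc_class_means(self, small_gt, small_genes):
        # k=1, noiseless: genotype-class means in ratio 1 : 1.5 : 2
        eff = pd.DataFrame(
            {
                "gene": [small_genes["gene"].iloc[0]],
                "variant": [small_gt.variants["variant"].iloc[0]],
                "log2_afc": [1.0],
                "tissues": [("T0",)],
            }
        )
        truth = SyntheticTruth(cis_effects=eff, trans_effects=pd.DataFrame(
            columns=["variant", "mediator_gene", "target_gene", "tissues", "effect"]
        ))
        (te,) = syn.simulate_multitissue_expression(
            small_gt, 1, 150, truth, noise_sd=0.0, n_latent=0, seed=5,
            genes=small_genes, tissue_names=["T0"],
        )
        g = small_gt.dosage[
            [small_gt.donors.index(d) for d in te.donors],
            0,
        ]
        y = te.values[0]
        means = [y[g == c].mean() for c in (0, 1, 2) if (g == c).any()]
        ratios = np.array(means) / means[0]
        np.testing.assert_allclose(ratios, [1.0, 1.5, 2.0][: len(ratios)],
                                   rtol=1e-9)

    def test_null_effects_give_uniform_p(self, small_gt, small_genes):
        # k=0 everywhere, no latent factors: per-gene regression p uniform
        truth = SyntheticTruth(
            cis_effects=pd.DataFrame(
                columns=["gene", "variant", "log2_afc", "tissues"]
            ),
            trans_effects=pd.DataFrame(
                columns=["variant", "mediator_gene", "target_gene",
                         "tissues", "effect"]
            ),
        )
        (te,) = syn.simulate_multitissue_expression(
            small_gt, 1, 150, truth, noise_sd=0.5, n_latent=0, seed=6,
            genes=small_genes, tissue_names=["T0"],
        )
        didx = [small_gt.donors.index(d) for d in te.donors]
        g = small_gt.dosage[didx, 0].astype(float)
        ps = []
        for row in np.log2(te.values):
            r = stats.pearsonr(g, row)
            ps.append(r.pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_determinism_and_donor_overlap(self, small_gt, small_genes,
                                           small_truth):
        kwargs = dict(noise_sd=0.4, n_latent=0, seed=7, genes=small_genes,
                      tissue_names=["T0", "T1"])
        a = syn.simulate_multitissue_expression(small_gt, 2, 120,
                                                small_truth, **kwargs)
        b = syn.simulate_multitissue_expression(small_gt, 2, 120,
                                                small_truth, **kwargs)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        shared = set(a[0].donors) & set(a[1].donors)
        assert len(shared) > 0  # overlapping donor subsets

    def test_unknown_gene_in_truth_rejected(self, small_gt, small_genes):
        bad = SyntheticTruth(
            cis_effects=pd.DataFrame(
                {"gene": ["NOPE"], "variant":
                 [small_gt.variants["variant"].iloc[0]],
                 "log2_afc": [1.0], "tissues": [("T0",)]}
            ),
            trans_effects=pd.DataFrame(
                columns=["variant", "mediator_gene", "target_gene",
                         "tissues", "effect"]
            ),
        )
        with pytest.raises(ValueError, match="unknown"):
            syn.simulate_multitissue_expression(
                small_gt, 1, 50, bad, seed=0, genes=small_genes,
                tissue_names=["T0"],
            )


class TestTruth:
    def test_trans_mediator_must_have_cis_effect(self):
        truth = SyntheticTruth(
            cis_effects=pd.DataFrame(
                {"gene": ["g1"], "variant": ["v1"], "log2_afc": [1.0],
                 "tissues": [("T0",)]}
            ),
            trans_effects=pd.DataFrame(
                {"variant": ["v2"], "mediator_gene": ["g1"],
                 "target_gene": ["g2"], "tissues": [("T0",)], "effect": [1.0]}
            ),
        )
        with pytest.raises(ValueError, match="mediator"):
            truth.validate()

    def test_make_truth_links_trans_to_cis(self, small_truth):
        small_truth.validate()
        assert len(small_truth.trans_effects) == 1
        med = small_truth.trans_effects.iloc[0]
        assert (
            (small_truth.cis_effects["gene"] == med["mediator_gene"])
            & (small_truth.cis_effects["variant"] == med["variant"])
        ).any()


@pytest.fixture(scope="module")
def ase_setup():
    gt = syn.simulate_genotypes(300, 40, (0.3, 0.5), 1, seed=21)
    genes = syn.simulate_gene_table(6, seed=22)
    return gt, genes


class TestAseCounts:
    def _alt_fraction_at_hets(self, gt, genes, k, eps, seed=23):
        eff = pd.DataFrame(
            {
                "gene": [genes["gene"].iloc[0]],
                "variant": [gt.variants["variant"].iloc[0]],
                "log2_afc": [k],
                "tissues": [("T0",)],
            }
        )
        truth = SyntheticTruth(
            cis_effects=eff,
            trans_effects=pd.DataFrame(
                columns=["variant", "mediator_gene", "target_gene",
                         "tissues", "effect"]
            ),
            phasing_error_rate=eps,
        )
        counts = syn.simulate_ase_counts(
            gt, truth, mean_depth=200.0, seed=seed, genes=genes,
            tissue_names=["T0"], n_sites_per_gene=2,
        )
        sub = counts[counts["gene"] == genes["gene"].iloc[0]]
        het = {
            gt.donors[i]
            for i in np.flatnonzero(gt.dosage[:, 0] == 1)
        }
        sub = sub[sub["donor"].isin(het) & (sub["total"] > 0)]
        # orient counts onto the haplotype carrying the eVariant alt allele
        vi = 0
        alt_on_hap1 = {
            gt.donors[i]: bool(gt.hap1[i, vi])
            for i in np.flatnonzero(gt.dosage[:, 0] == 1)
        }
        fracs, signed = [], []
        for _, row in sub.iterrows():
            site_alt_on_a = row["true_hap"] == "A"
            evar_on_a = alt_on_hap1[row["donor"]]
            aligned = site_alt_on_a == evar_on_a
            alt_hap_count = row["alt_count"] if aligned else row["ref_count"]
            fracs.append(alt_hap_count / row["total"])
            # phased (error-prone) version for the signed-imbalance check
            obs_aligned = (row["hap_assignment"] == "A") == evar_on_a
            obs_count = row["alt_count"] if obs_aligned else row["ref_count"]
            signed.append(obs_count / row["total"] - 0.5)
        return np.array(fracs), np.array(signed)

    def test_null_afc_balanced(self, ase_setup):
        gt, genes = ase_setup
        fracs, _ = self._alt_fraction_at_hets(gt, genes, k=0.0, eps=0.0)
        assert abs(fracs.mean() - 0.5) < 0.02

    def test_afc_one_gives_two_thirds(self, ase_setup):
        gt, genes = ase_setup
        fracs, _ = self._alt_fraction_at_hets(gt, genes, k=1.0, eps=0.0)
        assert abs(fracs.mean() - 2.0 / 3.0) < 0.02

    def test_worst_case_phasing_error_cancels_imbalance(self, ase_setup):
        # with 50% phasing error the signed imbalance averages to zero
        gt, genes = ase_setup
        _, signed = self._alt_fraction_at_hets(gt, genes, k=1.0, eps=0.5)
        assert abs(signed.mean()) < 0.03

    def test_counts_only_at_heterozygous_sites(self, ase_setup):
        gt, genes = ase_setup
        truth = SyntheticTruth(
            cis_effects=pd.DataFrame(
                columns=["gene", "variant", "log2_afc", "tissues"]
            ),
            trans_effects=pd.DataFrame(
                columns=["variant", "mediator_gene", "target_gene",
                         "tissues", "effect"]
            ),
        )
        counts = syn.simulate_ase_counts(
            gt, truth, mean_depth=30.0, seed=9, genes=genes.head(2),
            tissue_names=["T0"], n_sites_per_gene=1,
        )
        # every (donor, site) row corresponds to a site-level het: exactly
        # one haplotype carries the alternate allele, so both labels occur
        assert set(counts["true_hap"]) <= {"A", "B"}


class TestAnnotations:
    def test_pirna_coverage_near_target(self, small_gt, small_genes):
        tracks = syn.simulate_annotations(
            small_gt, small_genes, pirna_fraction=0.025, seed=31
        )
        pir = tracks.track("pirna")
        total = (pir["end"] - pir["start"]).sum()
        genome_len = sum(syn.DEFAULT_GENOME.values())
        assert abs(total - 0.025 * genome_len) <= 0.1 * 0.025 * genome_len

    def test_zero_fraction_zero_overlap(self, small_gt, small_genes):
        from tissueqtl.enrichment import interval_overlap

        tracks = syn.simulate_annotations(
            small_gt, small_genes, pirna_fraction=1e-9, seed=32
        )
        hit = interval_overlap(small_gt.variants, tracks.track("pirna"))
        assert hit.sum() == 0

    def test_deterministic(self, small_gt, small_genes):
        a = syn.simulate_annotations(small_gt, small_genes, 0.02, seed=33)
        b = syn.simulate_annotations(small_gt, small_genes, 0.02, seed=33)
        pd.testing.assert_frame_equal(a.track("pirna"), b.track("pirna"))

    def test_excluded_track_nonempty_and_clusters_avoid_it(
        self, small_gt, small_genes
    ):
        tracks = syn.simulate_annotations(
            small_gt, small_genes, 0.025, seed=34
        )
        exc = tracks.track("excluded")
        pir = tracks.track("pirna")
        assert len(exc) > 0
        for _, c in pir.iterrows():
            sub = exc[exc["chrom"] == c["chrom"]]
            assert not (
                (c["start"] < sub["end"]) & (sub["start"] < c["end"])
            ).any()
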