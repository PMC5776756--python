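"""Synthetic-data validation suite.

Each function runs one calibration or recovery study on data from the
synthetic generator under fixed study conditions and returns the measured
quantities: permutation/Beta-extrapolation agreement, eGene FDR
calibration, allelic-fold-change recovery, oracle equivalences for the
closed-form statistics, tissue-sharing recovery, cis-mediated trans
detection, and permutation-test calibration.  The functions are
deterministic given their seed and are the substance behind both the
acceptance tests and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from tissueqtl import synthetic as syn
from tissueqtl.ase import (
    afc_from_ase,
    afc_from_eqtl,
    aggregate_gene_haplotypes,
    binomial_two_sided_p,
    filter_ase_sites,
)
from tissueqtl.cis import call_egenes, map_cis_tissue, permutation_pass
from tissueqtl.coloc_mr import coloc_posteriors, mendelian_randomization
from tissueqtl.datatypes import GenotypeMatrix
from tissueqtl.enrichment import fisher_enrichment, permutation_cluster_test
from tissueqtl.fdr import bh_adjust
from tissueqtl.multi_tissue import (
    cluster_labels,
    m_values,
    m_values_sampled,
    pairwise_replication,
    sharing_summary,
)
from tissueqtl.preprocess import preprocess_tissue
from tissueqtl.regression import ols_scan
from tissueqtl.trans import bh_fdr, restricted_scan, trans_scan


def _local_genotypes(rng: np.random.Generator, n: int, m: int,
                     p: float = 0.3) -> GenotypeMatrix:
    """Independent biallelic variants local to one simulated gene."""
    dosage = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    af = dosage.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "variant": [f"v{i}" for i in range(m)],
            "chrom": "chr1",
            "pos": np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(af, 1 - af),
        }
    )
    return GenotypeMatrix(
        dosage=dosage, variants=variants,
        donors=[f"D{i:04d}" for i in range(n)],
    )


# ---------------------------------------------------------------- criterion 1

def beta_vs_direct(seed: int, n_genes: int = 200, n_perm: int = 1000,
                   n_samples: int = 150, m: int = 5) -> dict:
    """Agreement of Beta-extrapolated and direct permutation p-values.

    Simulates ``n_genes`` null genes, runs the permutation pass at a
    fixed permutation count, and reports the Spearman correlation between
    the two gene-level p-value definitions; also fits the Beta null to
    genes with M near-orthogonal variants and reports how far the fitted
    effective-test-count parameter lands from M.
    """
    rng = np.random.default_rng(seed)
    emp, direct = [], []
    for _ in range(n_genes):
        gt = _local_genotypes(rng, n_samples, m)
        y = rng.normal(size=n_samples)
        res, _ = permutation_pass(
            "g", np.arange(m), y, gt, np.arange(n_samples), None, "T0",
            n_min=n_perm, n_max=n_perm, seed=int(rng.integers(2**31)),
        )
        emp.append(res.p_empirical)
        direct.append(res.p_direct)
    rho = float(stats.spearmanr(emp, direct).statistic)

    rel_errs = []
    for m_orth in (4, 8, 12):
        for _ in range(5):
            gt = _local_genotypes(rng, 500, m_orth, p=0.5)
            y = rng.normal(size=500)
            res, _ = permutation_pass(
                "g", np.arange(m_orth), y, gt, np.arange(500), None, "T0",
                n_min=10_000, n_max=10_000, seed=int(rng.integers(2**31)),
            )
            rel_errs.append(abs(res.beta_n - m_orth) / m_orth)
    return {
        "spearman_rho": rho,
        "nhat_max_rel_err": float(max(rel_errs)),
        "nhat_mean_rel_err": float(np.mean(rel_errs)),
        "n_genes": n_genes,
    }


# ---------------------------------------------------------------- criterion 2

def _fdr_seed(seed: int, n_genes: int, frac_signal: float,
              n_samples: int, m: int, beta: float,
              fdr: float) -> tuple[int, int, float]:
    rng = np.random.default_rng(seed)
    n_sig = int(n_genes * frac_signal)
    rows = []
    for gi in range(n_genes):
        gt = _local_genotypes(rng, n_samples, m)
        y = rng.normal(size=n_samples)
        if gi < n_sig:
            y = y + beta * gt.dosage[:, 0]
        res, _ = permutation_pass(
            f"g{gi}", np.arange(m), y, gt, np.arange(n_samples), None,
            "T0", n_min=1000, n_max=10_000,
            seed=int(rng.integers(2**31)),
        )
        rows.append(
            {"gene": f"g{gi}", "p_empirical": res.p_empirical,
             "signal": gi < n_sig}
        )
    out = call_egenes(pd.DataFrame(rows), fdr=fdr)
    called = out[out["egene"]]
    n_false = int((~called["signal"]).sum())
    n_called = len(called)
    recall = called["signal"].sum() / n_sig if n_sig else np.nan
    return n_false, n_called, recall


def egene_fdr_calibration(
    seed: int, n_seeds: int = 20, n_null_seeds: int = 10,
    n_genes: int = 1000, frac_signal: float = 0.10,
    n_samples: int = 150, m: int = 5, beta: float = 0.6,
    fdr: float = 0.05,
) -> dict:
    """Realized eGene FDR under a mixed null/signal design, and false
    eGene counts under the global null."""
    rng = np.random.default_rng(seed)
    fdrs, recalls = [], []
    for _ in range(n_seeds):
        n_false, n_called, recall = _fdr_seed(
            int(rng.integers(2**31)), n_genes, frac_signal, n_samples, m,
            beta, fdr,
        )
        fdrs.append(n_false / max(n_called, 1))
        recalls.append(recall)
    null_false = []
    for _ in range(n_null_seeds):
        n_false, _, _ = _fdr_seed(
            int(rng.integers(2**31)), n_genes, 0.0, n_samples, m, beta,
            fdr,
        )
        null_false.append(n_false)
    return {
        "realized_fdr": float(np.mean(fdrs)),
        "mean_recall": float(np.mean(recalls)),
        "null_false_egenes_per_run": float(np.mean(null_false)),
        "null_false_egene_rate": float(np.mean(null_false) / n_genes),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------- criterion 3

def afc_recovery(seed: int, n_genes: int = 100, n_donors: int = 200,
                 mean_depth: float = 50.0) -> dict:
    """Planted log2 aFC recovery from eQTL data and from ASE counts."""
    gt = syn.simulate_genotypes(n_donors, 120, (0.2, 0.5), 1, seed=seed)
    genes = syn.simulate_gene_table(n_genes, seed=seed + 1)
    truth = syn.make_truth(
        gt, genes, ["T0"], seed + 2, n_cis=n_genes,
        afc_range=(0.5, 2.0), min_maf=0.2,
    )
    (te,) = syn.simulate_multitissue_expression(
        gt, 1, n_donors, truth, noise_sd=0.5, n_latent=0, seed=seed + 3,
        genes=genes, tissue_names=["T0"],
    )
    sel = [gt.donors.index(d) for d in te.donors]
    k_eqtl, k_true = {}, {}
    for _, eff in truth.cis_effects.iterrows():
        gi = genes.index[genes["gene"] == eff["gene"]][0]
        vi = gt.variant_index(eff["variant"])
        est = afc_from_eqtl(
            eff["gene"], eff["variant"], "T0", te.values[gi],
            gt.dosage[sel, vi], n_boot=0,
        )
        k_eqtl[eff["gene"]] = est.k
        k_true[eff["gene"]] = eff["log2_afc"]
    ke = np.array([k_eqtl[g] for g in k_true])
    kt = np.array(list(k_true.values()))
    rmse = float(np.sqrt(np.mean((ke - kt) ** 2)))

    ase = syn.simulate_ase_counts(
        gt, truth, mean_depth=mean_depth, seed=seed + 4, genes=genes,
        tissue_names=["T0"], n_sites_per_gene=2,
    )
    agg, _ = aggregate_gene_haplotypes(filter_ase_sites(ase))
    agg_idx = agg.set_index(["donor", "gene"])
    k_ase = {}
    for _, eff in truth.cis_effects.iterrows():
        vi = gt.variant_index(eff["variant"])
        het = np.flatnonzero(gt.dosage[:, vi] == 1)
        rows = []
        for i in het:
            key = (gt.donors[i], eff["gene"])
            if key not in agg_idx.index:
                continue
            sub = agg_idx.loc[key]
            rows.append(
                {
                    "hap_a_count": int(sub["hap_a_count"]),
                    "hap_b_count": int(sub["hap_b_count"]),
                    "evariant_alt_hap": "A" if gt.hap1[i, vi] else "B",
                }
            )
        if rows:
            k_ase[eff["gene"]] = afc_from_ase(
                eff["gene"], eff["variant"], "T0", pd.DataFrame(rows)
            ).k
    common = [g for g in k_true if g in k_ase]
    rho = float(
        stats.spearmanr(
            [k_eqtl[g] for g in common], [k_ase[g] for g in common]
        ).statistic
    )
    return {
        "afc_rmse_eqtl": rmse,
        "afc_spearman_eqtl_vs_ase": rho,
        "n_genes": len(common),
    }


# ---------------------------------------------------------------- criterion 4

def oracle_checks(seed: int) -> dict:
    """Exact-statistic oracles: max discrepancies across the board."""
    rng = np.random.default_rng(seed)

    # exact binomial vs scipy's exact test, all count pairs n <= 50
    binom_err = 0.0
    for n in range(1, 51):
        ks = np.arange(n + 1)
        ours = binomial_two_sided_p(ks, np.full(n + 1, n))
        for k, p in zip(ks, ours):
            binom_err = max(
                binom_err, abs(p - stats.binomtest(int(k), n, 0.5).pvalue)
            )

    # Fisher vs hypergeometric enumeration on random tables (n <= 200)
    fisher_err = 0.0
    for _ in range(40):
        nf = int(rng.integers(5, 100))
        nb = int(rng.integers(5, 100))
        focal = rng.random(nf) < rng.random()
        bg = rng.random(nb) < rng.random()
        res = fisher_enrichment(focal, bg)
        a, b, c, d = res["counts"]
        n = a + b + c + d
        k = a + c
        p_obs = stats.hypergeom.pmf(a, n, k, a + b)
        total = 0.0
        for x in range(max(0, k - (c + d)), min(k, a + b) + 1):
            px = stats.hypergeom.pmf(x, n, k, a + b)
            if px <= p_obs * (1 + 1e-9):
                total += px
        fisher_err = max(fisher_err, abs(res["p"] - min(total, 1.0)))

    # coloc vs brute-force configuration enumeration at 10-variant loci
    coloc_err = 0.0
    for _ in range(10):
        l1 = rng.normal(0, 3, 10)
        l2 = rng.normal(0, 3, 10)
        res = coloc_posteriors(l1, l2)
        a1, a2 = np.exp(l1), np.exp(l2)
        h = np.array(
            [
                1.0,
                1e-4 * a1.sum(),
                1e-4 * a2.sum(),
                1e-8 * (a1.sum() * a2.sum() - (a1 * a2).sum()),
                1e-5 * (a1 * a2).sum(),
            ]
        )
        coloc_err = max(coloc_err, float(np.abs(res.pp - h / h.sum()).max()))

    # exact m-value enumeration vs Monte-Carlo sampler at T=8
    m_err = 0.0
    for _ in range(5):
        beta = rng.normal(0, 0.3, 8)
        se = np.full(8, 0.15)
        exact = m_values(beta, se)
        mc = m_values_sampled(
            beta, se, n_samples=200_000, seed=int(rng.integers(2**31))
        )
        m_err = max(m_err, float(np.abs(exact - mc).max()))

    # nominal scan vs hand-rolled full-design OLS
    ols_err = 0.0
    for _ in range(20):
        n = 80
        g = rng.integers(0, 3, n).astype(float)
        c = rng.normal(size=(n, 3))
        y = 0.3 * g + c @ rng.normal(size=3) + rng.normal(size=n)
        res = ols_scan(y, g[:, None], covariates=c)
        x = np.column_stack([np.ones(n), c, g])
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        df = n - x.shape[1]
        cov = resid @ resid / df * np.linalg.inv(x.T @ x)
        beta, sebeta = coef[-1], np.sqrt(cov[-1, -1])
        p = 2 * stats.t.sf(abs(beta / sebeta), df)
        ols_err = max(
            ols_err,
            abs(res.beta[0] - beta), abs(res.se[0] - sebeta),
            abs(res.p[0] - p),
        )
    return {
        "binomial_max_abs_diff": float(binom_err),
        "fisher_max_abs_diff": float(fisher_err),
        "coloc_max_abs_diff": float(coloc_err),
        "mvalue_max_abs_diff": float(m_err),
        "ols_max_abs_diff": float(ols_err),
    }


# ---------------------------------------------------------------- criterion 5

def _per_tissue_effects(gt, genes, truth, tissues, seed, donors_per_tissue,
                        noise_sd=0.5):
    """Per-tissue OLS effects at the planted (gene, variant) pairs."""
    ts = syn.simulate_multitissue_expression(
        gt, len(tissues), donors_per_tissue, truth, noise_sd=noise_sd,
        n_latent=0, seed=seed, genes=genes, tissue_names=tissues,
    )
    rows = []
    norm_by_tissue = {}
    for te in ts:
        norm, cov = preprocess_tissue(te, k=0)
        norm_by_tissue[te.tissue] = (norm, cov)
        didx = [gt.donors.index(d) for d in norm.donors]
        kept = {g: i for i, g in enumerate(norm.kept_genes)}
        for _, eff in truth.cis_effects.iterrows():
            if eff["gene"] not in kept:
                continue
            vi = gt.variant_index(eff["variant"])
            r = ols_scan(
                norm.values[kept[eff["gene"]]],
                gt.dosage[didx, vi : vi + 1].astype(float),
                cov.matrix,
            )
            rows.append(
                {
                    "gene": eff["gene"], "variant": eff["variant"],
                    "tissue": te.tissue, "beta": r.beta[0],
                    "se": r.se[0], "p_nominal": r.p[0],
                }
            )
    return pd.DataFrame(rows), norm_by_tissue


def sharing_group_recovery(seed: int, n_seeds: int = 10) -> dict:
    """Three planted tissue groups: does 1-rho clustering recover them?"""
    from sklearn.metrics import adjusted_rand_score

    tissues = ["A1", "A2", "B1", "B2", "C1", "C2"]
    groups = {t: i // 2 for i, t in enumerate(tissues)}
    rng = np.random.default_rng(seed)
    successes = 0
    for _ in range(n_seeds):
        s = int(rng.integers(2**31 - 10))
        gt = syn.simulate_genotypes(150, 120, (0.2, 0.5), 1, seed=s)
        genes = syn.simulate_gene_table(60, seed=s + 1)
        truth = syn.make_truth(
            gt, genes, tissues, s + 2, n_cis=60, afc_range=(1.0, 2.0),
            min_maf=0.2,
        )
        truth.cis_effects["tissues"] = [
            tuple(t for t in tissues if groups[t] == i % 3)
            for i in range(len(truth.cis_effects))
        ]
        eff, _ = _per_tissue_effects(gt, genes, truth, tissues, s + 3, 130)
        sh = sharing_summary(eff)
        labels = cluster_labels(sh["linkage"], 3)
        ari = adjusted_rand_score([groups[t] for t in sh["tissues"]], labels)
        successes += ari == 1.0
    return {"ari_success_fraction": successes / n_seeds, "n_seeds": n_seeds}


def pi1_sharing_recovery(seed: int, n_seeds: int = 6,
                         n_cis: int = 400) -> dict:
    """pi1 replication of a planted 50% sharing fraction (mean over seeds)."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31 - 10))
        gt = syn.simulate_genotypes(250, 500, (0.2, 0.5), 1, seed=s)
        genes = syn.simulate_gene_table(int(n_cis * 1.15), seed=s + 1)
        truth = syn.make_truth(
            gt, genes, ["A", "B"], s + 2, n_cis=n_cis,
            afc_range=(1.0, 2.0), min_maf=0.2,
        )
        truth.cis_effects["tissues"] = [
            ("A", "B") if i % 2 == 0 else ("A",)
            for i in range(len(truth.cis_effects))
        ]
        pairs_df, _ = _per_tissue_effects(
            gt, genes, truth, ["A", "B"], s + 3, 220
        )
        pairs = {
            t: sub[["gene", "variant", "p_nominal"]].reset_index(drop=True)
            for t, sub in pairs_df.groupby("tissue")
        }
        disc = pairs["A"].copy()
        disc["padj"] = bh_adjust(disc["p_nominal"].to_numpy())
        disc = disc[disc["padj"] <= 0.05]
        rep = pairwise_replication({"A": disc}, pairs)
        vals.append(
            float(
                rep.set_index(["discovery", "replication"]).loc[
                    ("A", "B"), "pi1"
                ]
            )
        )
    return {"mean_pi1": float(np.mean(vals)), "planted_sharing": 0.5,
            "n_seeds": n_seeds}


def trans_vs_cis_m_sharing(seed: int) -> dict:
    """Tissue-specific trans effects share across fewer tissues than
    ubiquitous cis effects (m > 0.9 tissue counts)."""
    tissues = [f"T{i}" for i in range(6)]
    gt = syn.simulate_genotypes(200, 150, (0.2, 0.5), 1, seed=seed)
    genes = syn.simulate_gene_table(40, seed=seed + 1)
    truth = syn.make_truth(
        gt, genes, tissues, seed + 2, n_cis=8, n_trans=4,
        afc_range=(1.2, 2.0), min_maf=0.2,
    )
    # cis effects ubiquitous; mediated trans chains active in one tissue
    truth.cis_effects["tissues"] = [tuple(tissues)] * len(truth.cis_effects)
    rng = np.random.default_rng(seed + 3)
    truth.trans_effects["tissues"] = [
        (tissues[int(rng.integers(len(tissues)))],)
        for _ in range(len(truth.trans_effects))
    ]
    ts = syn.simulate_multitissue_expression(
        gt, 6, 170, truth, noise_sd=0.5, n_latent=0, seed=seed + 4,
        genes=genes, tissue_names=tissues,
    )
    rows = []
    for te in ts:
        norm, cov = preprocess_tissue(te, k=0)
        didx = [gt.donors.index(d) for d in norm.donors]
        kept = {g: i for i, g in enumerate(norm.kept_genes)}
        for kind, frame, gene_col in (
            ("cis", truth.cis_effects, "gene"),
            ("trans", truth.trans_effects, "target_gene"),
        ):
            for _, eff in frame.iterrows():
                gene = eff[gene_col]
                if gene not in kept:
                    continue
                vi = gt.variant_index(eff["variant"])
                r = ols_scan(
                    norm.values[kept[gene]],
                    gt.dosage[didx, vi : vi + 1].astype(float),
                    cov.matrix,
                )
                rows.append(
                    {"kind": kind, "gene": gene, "variant": eff["variant"],
                     "tissue": te.tissue, "beta": r.beta[0], "se": r.se[0]}
                )
    eff_df = pd.DataFrame(rows)
    shared = {}
    for kind, sub in eff_df.groupby("kind"):
        counts = []
        for _, grp in sub.groupby(["gene", "variant"]):
            m = m_values(grp["beta"].to_numpy(), grp["se"].to_numpy())
            counts.append(int((m > 0.9).sum()))
        shared[kind] = float(np.mean(counts))
    return {
        "mean_tissues_shared_cis": shared.get("cis", np.nan),
        "mean_tissues_shared_trans": shared.get("trans", np.nan),
    }


# ---------------------------------------------------------------- criterion 6

def mediation_detection(seed: int, n_seeds: int = 10) -> dict:
    """Planted variant -> cis gene -> trans gene chains: restricted-scan
    power versus genome-wide, and Mendelian-randomization p-values."""
    rng = np.random.default_rng(seed)
    tp_full = tp_restricted = 0
    n_planted = 0
    mr_success = 0
    n_mr = 0
    for _ in range(n_seeds):
        s = int(rng.integers(2**31 - 10))
        gt = syn.simulate_genotypes(300, 120, (0.2, 0.5), 4, seed=s)
        genes = syn.simulate_gene_table(30, seed=s + 1)
        truth = syn.make_truth(
            gt, genes, ["T0"], s + 2, n_cis=6, n_trans=3,
            afc_range=(1.0, 2.0), min_maf=0.2,
        )
        (te,) = syn.simulate_multitissue_expression(
            gt, 1, 280, truth, noise_sd=0.5, n_latent=2, seed=s + 3,
            genes=genes, tissue_names=["T0"],
        )
        norm, cov = preprocess_tissue(te, k=2)
        cis = map_cis_tissue(
            norm, cov, gt, n_min=300, n_max=3000, seed=s + 4
        )
        full = bh_fdr(trans_scan(gt, norm, cov), 0.10)
        rest = bh_fdr(
            restricted_scan(
                gt, norm, cov, "cis_evariants", cis_egenes=cis["egenes"]
            ),
            0.10,
        )
        planted = list(
            zip(truth.trans_effects["variant"],
                truth.trans_effects["target_gene"])
        )
        n_planted += len(planted)

        def _recovered(sig: pd.DataFrame, variant: str, gene: str) -> bool:
            # a planted chain counts as found if any significant variant
            # for its target gene tags the planted variant (r^2 >= 0.8);
            # the restricted scan tests top cis-eVariants, which may be
            # LD proxies of the planted variant
            hits = sig.loc[sig["gene"] == gene, "variant"]
            vi = gt.variant_index(variant)
            lead = gt.dosage[:, vi].astype(float)
            for v in hits:
                other = gt.dosage[:, gt.variant_index(v)].astype(float)
                if v == variant:
                    return True
                if lead.std() > 0 and other.std() > 0 and (
                    np.corrcoef(lead, other)[0, 1] ** 2 >= 0.8
                ):
                    return True
            return False

        tp_full += sum(_recovered(full, v, g) for v, g in planted)
        tp_restricted += sum(_recovered(rest, v, g) for v, g in planted)
        didx = [gt.donors.index(d) for d in norm.donors]
        kept = {g: i for i, g in enumerate(norm.kept_genes)}
        for _, tr in truth.trans_effects.iterrows():
            vi = gt.variant_index(tr["variant"])
            res = mendelian_randomization(
                gt.dosage[didx, vi].astype(float),
                norm.values[kept[tr["mediator_gene"]]],
                norm.values[kept[tr["target_gene"]]],
                covariates=cov.latent,
            )
            n_mr += 1
            mr_success += res.p < 0.01
    return {
        "trans_recall_genomewide": tp_full / n_planted,
        "trans_recall_restricted": tp_restricted / n_planted,
        "mr_success_rate": mr_success / n_mr,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------- criterion 7

def permutation_floor(seed: int, n_perm: int = 10_000) -> dict:
    """p attains 1/(n_perm + 1) when the observed overlap beats every
    permutation."""
    genome = {"chr1": 2_000_000, "chr2": 2_000_000}
    excluded = pd.DataFrame(
        {"chrom": ["chr1", "chr2"], "start": [950_000] * 2,
         "end": [1_050_000] * 2, "label": "x"}
    )
    clusters = pd.DataFrame(
        {"chrom": ["chr1", "chr2"], "start": [100_000, 300_000],
         "end": [120_000, 330_000], "label": "c"}
    )
    focal = pd.DataFrame(
        {
            "variant": ["a", "b", "c", "d"],
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "pos": [100_500, 119_900, 300_500, 329_900],
            "maf": 0.3,
        }
    )
    res = permutation_cluster_test(
        focal, clusters, excluded, genome, n_perm=n_perm, seed=seed,
        proximity=None,
    )
    return {"p": res["p"], "floor": 1.0 / (n_perm + 1),
            "observed": res["observed"]}


def permutation_uniformity(seed: int, n_reps: int = 500,
                           n_perm: int = 200) -> dict:
    """Uniformity of the permutation p under the null: focal variants and
    cluster locations both drawn from the test's own placement scheme."""
    genome = {"chr1": 2_000_000, "chr2": 2_000_000}
    excluded = pd.DataFrame(
        {"chrom": ["chr1", "chr2"], "start": [950_000] * 2,
         "end": [1_050_000] * 2, "label": "x"}
    )
    length = 100_000
    nvar = 20_000
    master = np.random.default_rng(seed)
    ps = []
    for _ in range(n_reps):
        rng = np.random.default_rng(int(master.integers(2**31 - 1)))
        rows = []
        for chrom, chrom_len in genome.items():
            exc = excluded[excluded["chrom"] == chrom].iloc[0]
            gaps = [(0, int(exc["start"])), (int(exc["end"]), chrom_len)]
            starts, widths = [], []
            for lo, hi in gaps:
                room = hi - lo - length
                if room >= 0:
                    starts.append(lo)
                    widths.append(room + 1)
            cum = np.cumsum(widths)
            for _ in range(5):
                u = int(rng.integers(0, cum[-1]))
                gi = int(np.searchsorted(cum, u, side="right"))
                off = u - (cum[gi - 1] if gi else 0)
                s = int(starts[gi] + off)
                rows.append(
                    {"chrom": chrom, "start": s, "end": s + length,
                     "label": "c"}
                )
        clusters = pd.DataFrame(rows).sort_values(
            ["chrom", "start"], ignore_index=True
        )
        pos = rng.integers(1, 2_000_000, nvar)
        chrom_arr = np.where(rng.random(nvar) < 0.5, "chr1", "chr2")
        focal = pd.DataFrame(
            {"variant": [f"v{i}" for i in range(nvar)],
             "chrom": chrom_arr, "pos": pos, "maf": 0.3}
        )
        r = permutation_cluster_test(
            focal, clusters, excluded, genome, n_perm=n_perm,
            seed=int(master.integers(2**31 - 1)), proximity=None,
        )
        ps.append(r["p"])
    ks = stats.kstest(ps, "uniform")
    return {"ks_p": float(ks.pvalue), "ks_stat": float(ks.statistic),
            "n_reps": n_reps}
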