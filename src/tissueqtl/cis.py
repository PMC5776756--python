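"""Per-tissue cis-eQTL mapping.

For each gene: variants within 1 Mb of the TSS (tissue MAF >= 0.01, minor
allele in >= 10 samples) are scanned by OLS of inverse-normal expression
on dosage with covariates; the top association is calibrated by adaptive
permutations (1,000 to 10,000 by default) with a Beta-distribution fit to
the permutation minimum p-values; gene-level empirical p-values are
corrected across genes with Storey q-values (eGene at q <= 0.05); a
per-gene nominal threshold back-computed from the Beta fit defines the
significant variant-gene pairs; and forward-backward stepwise regression
identifies conditionally independent signals per eGene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tissueqtl.datatypes import GenotypeMatrix
from tissueqtl.fdr import storey_qvalues
from tissueqtl.preprocess import CovariateSet, NormalizedExpression
from tissueqtl.regression import (
    beta_mle,
    covariate_basis,
    ols_scan,
    permutation_min_p,
    residualize,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1_000_000
MIN_TISSUE_MAF = 0.01
MIN_MINOR_SAMPLES = 10
#: Adaptive permutation scheme: at least N_MIN, at most N_MAX permutations;
#: stop at N_MIN if the observed minimum has already been beaten N_HITS times.
DEFAULT_N_MIN = 1_000
DEFAULT_N_MAX = 10_000
DEFAULT_N_HITS = 15


@dataclass
class GeneLevelResult:
    gene: str
    top_variant: str
    beta: float
    se: float
    p_min_nominal: float
    beta_k: float
    beta_n: float
    p_empirical: float
    p_direct: float
    n_perm: int


def cis_window_variants(
    gene_row: pd.Series,
    gt: GenotypeMatrix,
    tissue_donor_idx: np.ndarray,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Indices of testable cis-window variants for one gene.

    A variant qualifies when it sits on the gene's chromosome with
    ``|pos - TSS| <= window`` (closed interval), has tissue-level MAF
    >= 0.01, and its minor allele is observed in at least 10 samples of
    the tissue.
    """
    chrom = gene_row["chrom"]
    tss = int(gene_row["tss"])
    v = gt.variants
    if chrom not in set(v["chrom"]):
        logger.warning("gene %s on chromosome %s absent from genotypes",
                       gene_row.get("gene", "?"), chrom)
        return np.array([], dtype=int)
    in_window = (
        (v["chrom"] == chrom) & ((v["pos"] - tss).abs() <= window)
    ).to_numpy()
    idx = np.flatnonzero(in_window)
    if idx.size == 0:
        return idx
    dose = gt.dosage[np.ix_(tissue_donor_idx, idx)]
    af = dose.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    minor_is_alt = af <= 0.5
    carriers_alt = (dose > 0).sum(axis=0)
    carriers_ref = (dose < 2).sum(axis=0)
    minor_carriers = np.where(minor_is_alt, carriers_alt, carriers_ref)
    ok = (maf >= MIN_TISSUE_MAF) & (minor_carriers >= MIN_MINOR_SAMPLES)
    return idx[ok]


def nominal_scan(
    gene: str,
    variant_idx: np.ndarray,
    y: np.ndarray,
    gt: GenotypeMatrix,
    tissue_donor_idx: np.ndarray,
    covariates: np.ndarray | None,
    tissue: str,
) -> pd.DataFrame:
    """EqtlRecord table for one gene against its cis-window variants."""
    g = gt.dosage[np.ix_(tissue_donor_idx, variant_idx)].astype(float)
    res = ols_scan(y, g, covariates)
    return pd.DataFrame(
        {
            "gene": gene,
            "variant": gt.variants["variant"].to_numpy()[variant_idx],
            "tissue": tissue,
            "beta": res.beta,
            "se": res.se,
            "t": res.t,
            "p_nominal": res.p,
        }
    )


def _select_top(records: pd.DataFrame, gt: GenotypeMatrix) -> pd.Series:
    """Top variant: smallest p, then largest |t|, then smallest position."""
    r = records.copy()
    pos = gt.variants.set_index("variant")["pos"]
    r["_pos"] = r["variant"].map(pos)
    r["_abst"] = -r["t"].abs()
    r = r.sort_values(["p_nominal", "_abst", "_pos"], kind="stable")
    return r.iloc[0]


def permutation_pass(
    gene: str,
    variant_idx: np.ndarray,
    y: np.ndarray,
    gt: GenotypeMatrix,
    tissue_donor_idx: np.ndarray,
    covariates: np.ndarray | None,
    tissue: str,
    n_min: int = DEFAULT_N_MIN,
    n_max: int = DEFAULT_N_MAX,
    n_hits: int = DEFAULT_N_HITS,
    seed: int = 0,
) -> tuple[GeneLevelResult, pd.DataFrame]:
    """Adaptive-permutation empirical p for one gene.

    Permutes the phenotype across samples (covariates fixed), records the
    minimum nominal p per permutation, stops after ``n_min`` permutations
    once the observed minimum has been beaten ``n_hits`` times, and fits
    a Beta distribution to the permutation minima by maximum likelihood.
    The Beta CDF evaluated at the observed minimum is the extrapolated
    empirical p; the direct counting estimate
    ``(1 + #{perm <= obs}) / (1 + N)`` is reported alongside.
    """
    if n_min > n_max:
        raise ValueError("n_min must not exceed n_max")
    if n_max < 100:
        raise ValueError("fewer than 100 permutations makes the Beta fit unstable")
    records = nominal_scan(
        gene, variant_idx, y, gt, tissue_donor_idx, covariates, tissue
    )
    top = _select_top(records, gt)
    p_obs = float(top["p_nominal"])

    n = y.shape[0]
    qb = covariate_basis(covariates, n)
    g = gt.dosage[np.ix_(tissue_donor_idx, variant_idx)].astype(float)
    g_res = residualize(g, qb)
    rng = np.random.default_rng(seed)
    minima = permutation_min_p(y, g_res, qb, n_min, rng)
    hits = int((minima <= p_obs).sum())
    if hits < n_hits and n_max > n_min:
        extra = permutation_min_p(y, g_res, qb, n_max - n_min, rng)
        minima = np.concatenate([minima, extra])
        hits = int((minima <= p_obs).sum())
    n_perm = minima.size
    k_hat, n_hat = beta_mle(minima)
    p_emp = float(stats.beta.cdf(p_obs, k_hat, n_hat))
    p_direct = (1.0 + hits) / (1.0 + n_perm)
    result = GeneLevelResult(
        gene=gene,
        top_variant=str(top["variant"]),
        beta=float(top["beta"]),
        se=float(top["se"]),
        p_min_nominal=p_obs,
        beta_k=k_hat,
        beta_n=n_hat,
        p_empirical=p_emp,
        p_direct=p_direct,
        n_perm=n_perm,
    )
    return result, records


def call_egenes(results: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Storey q-values over gene-level empirical p; eGene iff q <= fdr."""
    out = results.copy()
    if len(out) < 10:
        logger.warning("pi0 estimation with < 10 genes; pi0 fixed at 1")
    p = out["p_empirical"].to_numpy(float)
    if len(out) and np.all(p == p[0]):
        logger.warning("all empirical p identical; q = p * pi0")
    q, pi0 = storey_qvalues(p)
    out["q_value"] = q
    out["egene"] = out["q_value"] <= fdr
    out.attrs["pi0"] = pi0
    return out


def empirical_p_cut(
    results: pd.DataFrame, convention: str = "midpoint"
) -> float | None:
    """Empirical-p significance boundary for the tissue.

    ``midpoint``: halfway between the largest significant and smallest
    non-significant gene-level empirical p; ``max``: the largest
    significant empirical p itself.  None when no gene is significant.
    """
    sig = results.loc[results["egene"], "p_empirical"]
    if sig.empty:
        return None
    hi = float(sig.max())
    if convention == "max":
        return hi
    nonsig = results.loc[~results["egene"], "p_empirical"]
    if nonsig.empty:
        return hi
    return 0.5 * (hi + float(nonsig.min()))


def gene_nominal_threshold(beta_k: float, beta_n: float, p_cut: float) -> float:
    """Nominal-p threshold: inverse Beta CDF of the empirical-p boundary."""
    return float(stats.beta.ppf(p_cut, beta_k, beta_n))


def significant_pairs(
    results: pd.DataFrame,
    all_records: pd.DataFrame,
    convention: str = "midpoint",
) -> pd.DataFrame:
    """All variant-gene pairs below each eGene's nominal threshold."""
    cut = empirical_p_cut(results, convention)
    if cut is None:
        return all_records.iloc[0:0].assign(nominal_threshold=np.nan)
    thresholds = {
        row["gene"]: gene_nominal_threshold(row["beta_k"], row["beta_n"], cut)
        for _, row in results[results["egene"]].iterrows()
    }
    rec = all_records[all_records["gene"].isin(thresholds)].copy()
    rec["nominal_threshold"] = rec["gene"].map(thresholds)
    return rec[rec["p_nominal"] <= rec["nominal_threshold"]].reset_index(
        drop=True
    )


def stepwise_conditional(
    gene: str,
    variant_idx: np.ndarray,
    y: np.ndarray,
    gt: GenotypeMatrix,
    tissue_donor_idx: np.ndarray,
    covariates: np.ndarray | None,
    tissue: str,
    p_cut: float,
    n_perm: int = 1_000,
    seed: int = 0,
    max_signals: int = 10,
) -> pd.DataFrame:
    """Forward-backward stepwise search for independent cis signals.

    FORWARD: repeatedly add the top remaining variant whose
    permutation-calibrated empirical p (with previously selected variants
    as covariates) stays below the gene's empirical-p boundary.
    BACKWARD: re-test each selected variant with all others in the model
    and drop any whose empirical p no longer clears the boundary.
    """
    n = y.shape[0]
    base = (
        covariates
        if covariates is not None
        else np.ones((n, 1))
    )
    var_ids = gt.variants["variant"].to_numpy()[variant_idx]
    g_all = gt.dosage[np.ix_(tissue_donor_idx, variant_idx)].astype(float)
    rng = np.random.default_rng(seed)

    def _empirical(cov: np.ndarray) -> tuple[pd.Series, float, tuple[float, float]]:
        qb = covariate_basis(cov, n)
        g_res = residualize(g_all, qb)
        records = pd.DataFrame(
            {
                "gene": gene,
                "variant": var_ids,
                "tissue": tissue,
            }
        )
        res = ols_scan(y, g_all, cov, q_basis=qb, g_resid=g_res)
        records["beta"], records["se"] = res.beta, res.se
        records["t"], records["p_nominal"] = res.t, res.p
        top = _select_top(records, gt)
        minima = permutation_min_p(
            y, g_res, qb, n_perm, np.random.default_rng(int(rng.integers(2**31)))
        )
        k_hat, n_hat = beta_mle(minima)
        p_emp = float(stats.beta.cdf(top["p_nominal"], k_hat, n_hat))
        return top, p_emp, (k_hat, n_hat)

    selected: list[dict] = []
    cov = base
    for _rank in range(max_signals):
        top, p_emp, shape = _empirical(cov)
        if p_emp > p_cut:
            break
        sel_idx = int(np.flatnonzero(var_ids == top["variant"])[0])
        g_new = g_all[:, [sel_idx]]
        test = np.hstack([cov, g_new])
        if np.linalg.matrix_rank(test) < test.shape[1]:
            logger.warning(
                "variant %s collinear with selected set; rejected",
                top["variant"],
            )
            break
        selected.append(
            {
                "variant": str(top["variant"]),
                "idx": sel_idx,
                "beta": float(top["beta"]),
                "se": float(top["se"]),
                "p_nominal": float(top["p_nominal"]),
                "p_empirical": p_emp,
            }
        )
        cov = test

    # Backward: re-test each signal against the model holding the others.
    surviving: list[dict] = []
    if len(selected) > 1:
        for i, sig in enumerate(selected):
            others = [s["idx"] for j, s in enumerate(selected) if j != i]
            cov_i = np.hstack([base, g_all[:, others]])
            qb = covariate_basis(cov_i, n)
            g_res = residualize(g_all, qb)
            res = ols_scan(y, g_all, cov_i, q_basis=qb, g_resid=g_res)
            p_nom = float(res.p[sig["idx"]])
            minima = permutation_min_p(
                y, g_res, qb, n_perm,
                np.random.default_rng(int(rng.integers(2**31))),
            )
            k_hat, n_hat = beta_mle(minima)
            p_emp = float(stats.beta.cdf(p_nom, k_hat, n_hat))
            if p_emp <= p_cut:
                surviving.append(
                    {
                        **sig,
                        "beta": float(res.beta[sig["idx"]]),
                        "se": float(res.se[sig["idx"]]),
                        "p_nominal": p_nom,
                        "p_empirical": p_emp,
                    }
                )
    else:
        surviving = selected

    out = pd.DataFrame(
        surviving,
        columns=["variant", "idx", "beta", "se", "p_nominal", "p_empirical"],
    ).drop(columns=["idx"])
    out.insert(0, "gene", gene)
    out.insert(1, "tissue", tissue)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def map_cis_tissue(
    norm: NormalizedExpression,
    cov: CovariateSet | None,
    gt: GenotypeMatrix,
    window: int = DEFAULT_WINDOW,
    fdr: float = 0.05,
    n_min: int = DEFAULT_N_MIN,
    n_max: int = DEFAULT_N_MAX,
    seed: int = 0,
    convention: str = "midpoint",
    run_stepwise: bool = False,
) -> dict[str, pd.DataFrame]:
    """Full cis pass for one tissue.

    Returns a dict with ``egenes`` (gene-level results with q-values),
    ``pairs`` (all nominal records), ``signif_pairs`` and, optionally,
    ``conditional`` (stepwise independent signals).
    """
    donor_idx = np.array(
        [gt.donors.index(d) for d in norm.donors], dtype=int
    )
    cov_matrix = cov.matrix if cov is not None else None
    gene_results: list[GeneLevelResult] = []
    all_records: list[pd.DataFrame] = []
    rng = np.random.default_rng(seed)
    for gi, grow in norm.genes.iterrows():
        vidx = cis_window_variants(grow, gt, donor_idx, window)
        if vidx.size == 0:
            continue
        res, records = permutation_pass(
            grow["gene"],
            vidx,
            norm.values[gi],
            gt,
            donor_idx,
            cov_matrix,
            norm.tissue,
            n_min=n_min,
            n_max=n_max,
            seed=int(rng.integers(2**31)),
        )
        gene_results.append(res)
        all_records.append(records)
    egenes = pd.DataFrame([vars(r) for r in gene_results])
    pairs = (
        pd.concat(all_records, ignore_index=True)
        if all_records
        else pd.DataFrame()
    )
    if egenes.empty:
        return {"egenes": egenes, "pairs": pairs,
                "signif_pairs": pairs, "conditional": pd.DataFrame()}
    egenes = call_egenes(egenes, fdr=fdr)
    sig = significant_pairs(egenes, pairs, convention)
    out = {"egenes": egenes, "pairs": pairs, "signif_pairs": sig}
    if run_stepwise:
        cut = empirical_p_cut(egenes, convention)
        cond = []
        if cut is not None:
            for _, row in egenes[egenes["egene"]].iterrows():
                grow = norm.genes[norm.genes["gene"] == row["gene"]].iloc[0]
                gi = norm.genes.index[norm.genes["gene"] == row["gene"]][0]
                vidx = cis_window_variants(grow, gt, donor_idx, window)
                cond.append(
                    stepwise_conditional(
                        row["gene"], vidx, norm.values[gi], gt, donor_idx,
                        cov_matrix, norm.tissue, cut,
                        seed=int(rng.integers(2**31)),
                    )
                )
        out["conditional"] = (
            pd.concat(cond, ignore_index=True) if cond else pd.DataFrame()
        )
    return out
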