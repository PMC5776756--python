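"""Trans-eQTL mapping: cross-chromosome association scans.

Every protein-coding or lincRNA gene is tested against all variants on
other chromosomes (or at least 5 Mb from the TSS in intra-chromosomal
mode) with MAF > 0.05, using the same linear model and covariates as the
cis scan.  Artifact filters remove genes with poor mappability, variants
in repeat regions, and locus pairs with read cross-mapping evidence.
FDR is Benjamini-Hochberg within each tissue (default 10%).  Restricted
scans repeat the test over LD-pruned variants, top cis-eVariants, or
GWAS-catalog variants, with the FDR family limited to the restricted set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tissueqtl.datatypes import GenotypeMatrix
from tissueqtl.fdr import bh_adjust
from tissueqtl.preprocess import CovariateSet, NormalizedExpression
from tissueqtl.regression import covariate_basis, ols_scan, residualize

logger = logging.getLogger(__name__)


@dataclass
class TransScanConfig:
    maf_min: float = 0.05
    gene_biotypes: tuple[str, ...] = ("protein_coding", "lincRNA")
    fdr: float = 0.10
    min_tss_distance: int = 5_000_000
    intra_chromosomal: bool = False
    variant_block: int = 2_000
    max_pairs: int = 50_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must lie in (0, 1)")


@dataclass
class CrossMapPairList:
    """Artifact lists: cross-mapping locus pairs, mappability, repeats.

    ``cross_map`` holds symmetric (locus_a, locus_b) pairs keyed by
    (variant locus, gene locus) identifiers; ``gene_mappability`` maps
    gene -> score in [0, 1]; ``repeat_variants`` is the set of
    repeat-flagged variant ids.
    """

    cross_map: set[tuple[str, str]] = field(default_factory=set)
    gene_mappability: dict[str, float] = field(default_factory=dict)
    repeat_variants: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.cross_map = {
            pair for a, b in self.cross_map for pair in [(a, b), (b, a)]
        }


def trans_scan(
    gt: GenotypeMatrix,
    norm: NormalizedExpression,
    cov: CovariateSet | None,
    cfg: TransScanConfig | None = None,
    variant_subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Nominal trans associations for one tissue.

    Streams variants in blocks so memory stays O(block x genes).
    ``variant_subset`` restricts the scan to the given variant indices
    (used by the restricted scans).
    """
    cfg = cfg or TransScanConfig()
    donor_idx = np.array([gt.donors.index(d) for d in norm.donors], dtype=int)
    genes = norm.genes
    gene_ok = genes["biotype"].isin(cfg.gene_biotypes).to_numpy()
    if variant_subset is None:
        dose_t = gt.dosage[donor_idx]
        af = dose_t.mean(axis=0) / 2.0
        maf = np.minimum(af, 1.0 - af)
        variant_subset = np.flatnonzero(maf > cfg.maf_min)
    variant_subset = np.asarray(variant_subset, dtype=int)

    n_pairs = variant_subset.size * int(gene_ok.sum())
    if n_pairs > cfg.max_pairs:
        raise MemoryError(
            f"{n_pairs} variant-gene pairs exceed the configured cap; "
            "raise max_pairs or restrict the variant set"
        )

    n = len(donor_idx)
    cov_matrix = cov.matrix if cov is not None else None
    qb = covariate_basis(cov_matrix, n)
    df = n - qb.shape[1] - 1
    y = norm.values[gene_ok]  # genes x samples
    y_res = (y.T - qb @ (qb.T @ y.T)).T
    y_norm = np.linalg.norm(y_res, axis=1)
    gene_ids = genes["gene"].to_numpy()[gene_ok]
    gene_chrom = genes["chrom"].to_numpy()[gene_ok]
    gene_tss = genes["tss"].to_numpy()[gene_ok].astype(int)

    from scipy import stats as sps

    out_frames: list[pd.DataFrame] = []
    vtab = gt.variants
    for start in range(0, variant_subset.size, cfg.variant_block):
        block = variant_subset[start : start + cfg.variant_block]
        g = gt.dosage[np.ix_(donor_idx, block)].astype(float)
        g_res = residualize(g, qb)
        g_norm = np.linalg.norm(g_res, axis=0)
        ok_g = g_norm > 1e-10
        v_chrom = vtab["chrom"].to_numpy()[block]
        v_pos = vtab["pos"].to_numpy()[block].astype(int)
        if cfg.intra_chromosomal:
            testable = (v_chrom[None, :] == gene_chrom[:, None]) & (
                np.abs(v_pos[None, :] - gene_tss[:, None])
                >= cfg.min_tss_distance
            )
        else:
            testable = v_chrom[None, :] != gene_chrom[:, None]
        testable &= ok_g[None, :]
        if not testable.any():
            continue
        num = y_res @ g_res  # genes x block
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / (y_norm[:, None] * g_norm[None, :])
        r = np.clip(np.nan_to_num(r), -1.0, 1.0)
        gi, vi = np.nonzero(testable)
        rr = r[gi, vi]
        with np.errstate(divide="ignore"):
            t = rr * np.sqrt(df / np.maximum(1.0 - rr**2, 1e-300))
        p = 2.0 * sps.t.sf(np.abs(t), df)
        # slope and se on the residualized scale (exact full-model values)
        gtg = g_norm[vi] ** 2
        beta = num[gi, vi] / gtg
        yty = y_norm[gi] ** 2
        rss = np.maximum(yty - beta**2 * gtg, 0.0)
        se = np.sqrt(rss / df / gtg)
        out_frames.append(
            pd.DataFrame(
                {
                    "gene": gene_ids[gi],
                    "variant": vtab["variant"].to_numpy()[block][vi],
                    "tissue": norm.tissue,
                    "beta": beta,
                    "se": se,
                    "t": t,
                    "p_nominal": p,
                }
            )
        )
    if not out_frames:
        return pd.DataFrame(
            columns=["gene", "variant", "tissue", "beta", "se", "t", "p_nominal"]
        )
    return pd.concat(out_frames, ignore_index=True)


def apply_artifact_filters(
    records: pd.DataFrame,
    lists: CrossMapPairList,
    mappability_min: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records that match any artifact list; count reasons.

    Returns (filtered records, report) where the report counts drops per
    reason: ``low_mappability``, ``repeat``, ``crossmap``.
    """
    rec = records.copy()
    mapp = rec["gene"].map(lists.gene_mappability).fillna(1.0)
    drop_map = mapp < mappability_min
    drop_rep = rec["variant"].isin(lists.repeat_variants)
    pair_keys = list(zip(rec["variant"], rec["gene"]))
    drop_cross = np.array(
        [key in lists.cross_map for key in pair_keys], dtype=bool
    )
    report = pd.DataFrame(
        {
            "reason": ["low_mappability", "repeat", "crossmap"],
            "n_dropped": [
                int(drop_map.sum()),
                int(drop_rep.sum()),
                int(drop_cross.sum()),
            ],
        }
    )
    keep = ~(drop_map.to_numpy() | drop_rep.to_numpy() | drop_cross)
    return rec[keep].reset_index(drop=True), report


def bh_fdr(records: pd.DataFrame, fdr: float = 0.10) -> pd.DataFrame:
    """Benjamini-Hochberg step-up over all tested pairs in the family."""
    out = records.copy()
    out["p_adjusted"] = bh_adjust(out["p_nominal"].to_numpy(float))
    return out[out["p_adjusted"] <= fdr].reset_index(drop=True)


def ld_prune(
    gt: GenotypeMatrix,
    r2_max: float = 0.5,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Greedy sliding-window LD pruning (plink ``--indep``-style).

    Within each window of ``window`` variants (sliding by ``step``), any
    pair with r^2 > ``r2_max`` loses one member: the lower-MAF variant is
    removed (position tie-break: keep the smaller position).  Returns the
    retained variant indices.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must lie in (0, 1]")
    n_var = gt.n_variants
    keep = np.ones(n_var, dtype=bool)
    dose = gt.dosage.astype(float)
    maf = gt.variants["maf"].to_numpy(float)
    pos = gt.variants["pos"].to_numpy(int)
    chrom = gt.variants["chrom"].to_numpy()
    for start in range(0, n_var, step):
        idx = np.arange(start, min(start + window, n_var))
        idx = idx[keep[idx]]
        if idx.size < 2:
            continue
        sub = dose[:, idx]
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(sub.T)
        r2 = np.nan_to_num(r) ** 2
        np.fill_diagonal(r2, 0.0)
        changed = True
        while changed:
            changed = False
            pairs = np.argwhere(r2 > r2_max)
            if pairs.size == 0:
                break
            i, j = pairs[0]
            a, b = idx[i], idx[j]
            if chrom[a] != chrom[b]:
                r2[i, j] = r2[j, i] = 0.0
                changed = True
                continue
            if maf[a] < maf[b] or (maf[a] == maf[b] and pos[a] > pos[b]):
                drop_local, drop_global = i, a
            else:
                drop_local, drop_global = j, b
            keep[drop_global] = False
            r2[drop_local, :] = 0.0
            r2[:, drop_local] = 0.0
            changed = True
    return np.flatnonzero(keep)


def restricted_scan(
    gt: GenotypeMatrix,
    norm: NormalizedExpression,
    cov: CovariateSet | None,
    subset: str,
    cfg: TransScanConfig | None = None,
    *,
    cis_egenes: pd.DataFrame | None = None,
    gwas_catalog: pd.DataFrame | None = None,
    gwas_p_max: float = 2.0e-5,
    ld_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Trans scan over a reduced variant family.

    subset: ``ld_pruned`` (greedy r^2 pruning), ``cis_evariants`` (top
    cis-eVariant per eGene), or ``gwas`` (catalog variants with
    ``p <= gwas_p_max``).  BH FDR downstream must use only this family.
    """
    cfg = cfg or TransScanConfig()
    vids = gt.variants["variant"]
    if subset == "ld_pruned":
        idx = ld_prune(gt, **(ld_kwargs or {}))
    elif subset == "cis_evariants":
        if cis_egenes is None:
            raise ValueError("cis mapping results required for cis_evariants subset")
        tops = cis_egenes.loc[cis_egenes.get("egene", True), "top_variant"]
        idx = np.flatnonzero(vids.isin(set(tops)))
    elif subset == "gwas":
        if gwas_catalog is None:
            raise ValueError("GWAS catalog required for gwas subset")
        hits = gwas_catalog.loc[gwas_catalog["p"] <= gwas_p_max, "variant"]
        idx = np.flatnonzero(vids.isin(set(hits)))
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if idx.size == 0:
        logger.warning("restricted scan: empty %s variant subset", subset)
        return pd.DataFrame(
            columns=["gene", "variant", "tissue", "beta", "se", "t", "p_nominal"]
        )
    # Re-apply the MAF floor within the restricted family.
    donor_idx = np.array([gt.donors.index(d) for d in norm.donors], dtype=int)
    dose_t = gt.dosage[np.ix_(donor_idx, idx)]
    af = dose_t.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    idx = idx[maf > cfg.maf_min]
    return trans_scan(gt, norm, cov, cfg, variant_subset=idx)
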