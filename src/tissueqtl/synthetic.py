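"""Synthetic genotype, expression, ASE and annotation generator.

The generator plants known regulatory effects so that every downstream
stage (cis/trans mapping, tissue sharing, ASE, colocalization, mediation)
can be scored against ground truth:

* genotypes are hard-call biallelic dosages with a configurable MAF
  spectrum and block LD produced by a copy-with-mutation scheme;
* expression follows an additive allelic-fold-change model in cis
  (a genotype-``g`` donor's expected abundance scales with
  ``((2-g) + g*2**k) / 2`` for log2 aFC ``k``), with trans effects
  propagated linearly through a cis-regulated mediator gene, shared latent
  confounders, and multiplicative log-normal noise;
* allele-specific read counts are drawn at heterozygous transcribed sites
  with negative-binomial depth and an alt-haplotype read fraction of
  ``2**k / (1 + 2**k)`` in eVariant heterozygotes, with haplotype
  assignments flipped at a configurable phasing-error rate;
* annotation tracks (piRNA-like clusters, excluded regions, chromatin
  states, a GWAS catalog) cover configurable genome fractions.

The default genome is a small multi-chromosome coordinate system
(5 chromosomes x 2 Mb) so cross-chromosome trans analyses run at desk
scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tissueqtl.datatypes import (
    AnnotationTracks,
    GenotypeMatrix,
    SyntheticTruth,
    TissueExpression,
)

#: Default genome model: chromosome name -> length in bp.
DEFAULT_GENOME: dict[str, int] = {f"chr{i}": 2_000_000 for i in range(1, 6)}

#: Per-haplotype flip probability in the copy-with-mutation LD scheme.
DEFAULT_MUTATION_RATE = 0.05


def _check_positive(**kwargs: int) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def simulate_genotypes(
    n_donors: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 10,
    seed: int = 0,
    *,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    genome: dict[str, int] | None = None,
) -> GenotypeMatrix:
    """Simulate phased hard-call genotypes with block LD.

    Variants are laid out across the genome in consecutive LD blocks of
    ``ld_block_size`` variants.  The first variant of each block (the
    anchor) draws independent haplotypes at an allele frequency sampled
    from ``maf_range``; every other variant in the block copies the
    anchor's haplotypes, flipping each haplotype allele with probability
    ``mutation_rate``.  Blocks are mutually independent, so
    ``ld_block_size=1`` yields (asymptotically) uncorrelated variants.

    Parameters
    ----------
    maf_range : closed interval within (0, 0.5] for anchor allele
        frequencies.  Non-anchor variants inherit the anchor frequency up
        to the mutation perturbation ``p*(1-2m) + m``.
    """
    if n_donors < 2:
        raise ValueError("n_donors must be at least 2")
    _check_positive(n_variants=n_variants, ld_block_size=ld_block_size)
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a subinterval of (0, 0.5]")
    if not (0.0 <= mutation_rate < 0.5):
        raise ValueError("mutation_rate must lie in [0, 0.5)")
    genome = dict(genome or DEFAULT_GENOME)
    rng = np.random.default_rng(seed)

    chroms = list(genome)
    # Spread variants over chromosomes; keep blocks within one chromosome.
    per_chrom = np.full(len(chroms), n_variants // len(chroms))
    per_chrom[: n_variants % len(chroms)] += 1

    hap1 = np.empty((n_donors, n_variants), dtype=np.int8)
    hap2 = np.empty((n_donors, n_variants), dtype=np.int8)
    chrom_col: list[str] = []
    pos_col: list[int] = []
    col = 0
    for chrom, n_on_chrom in zip(chroms, per_chrom):
        if n_on_chrom == 0:
            continue
        positions = np.sort(
            rng.choice(
                np.arange(1, genome[chrom] + 1), size=n_on_chrom, replace=False
            )
        )
        done = 0
        while done < n_on_chrom:
            block = min(ld_block_size, n_on_chrom - done)
            p = rng.uniform(lo, hi)
            anchor1 = (rng.random(n_donors) < p).astype(np.int8)
            anchor2 = (rng.random(n_donors) < p).astype(np.int8)
            for j in range(block):
                if j == 0:
                    h1, h2 = anchor1, anchor2
                else:
                    flip1 = rng.random(n_donors) < mutation_rate
                    flip2 = rng.random(n_donors) < mutation_rate
                    h1 = np.where(flip1, 1 - anchor1, anchor1).astype(np.int8)
                    h2 = np.where(flip2, 1 - anchor2, anchor2).astype(np.int8)
                hap1[:, col] = h1
                hap2[:, col] = h2
                col += 1
            chrom_col.extend([chrom] * block)
            pos_col.extend(positions[done : done + block].tolist())
            done += block

    dosage = (hap1 + hap2).astype(np.int8)
    af = dosage.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    variants = pd.DataFrame(
        {
            "variant": [f"{c}_{p}" for c, p in zip(chrom_col, pos_col)],
            "chrom": chrom_col,
            "pos": pos_col,
            "ref": "A",
            "alt": "G",
            "maf": maf,
        }
    )
    donors = [f"D{i:04d}" for i in range(n_donors)]
    gt = GenotypeMatrix(
        dosage=dosage, variants=variants, donors=donors, hap1=hap1, hap2=hap2
    )
    gt.validate()
    return gt


def simulate_gene_table(
    n_genes: int,
    seed: int = 0,
    *,
    genome: dict[str, int] | None = None,
    lincrna_fraction: float = 0.1,
    other_fraction: float = 0.05,
) -> pd.DataFrame:
    """Random gene annotation: id, chromosome, TSS, strand, biotype."""
    _check_positive(n_genes=n_genes)
    genome = dict(genome or DEFAULT_GENOME)
    rng = np.random.default_rng(seed)
    chroms = rng.choice(list(genome), size=n_genes)
    tss = np.array([rng.integers(1, genome[c] + 1) for c in chroms])
    strand = rng.choice(["+", "-"], size=n_genes)
    biotype = rng.choice(
        ["protein_coding", "lincRNA", "other"],
        size=n_genes,
        p=[1 - lincrna_fraction - other_fraction, lincrna_fraction, other_fraction],
    )
    genes = pd.DataFrame(
        {
            "gene": [f"G{i:04d}" for i in range(n_genes)],
            "chrom": chroms,
            "tss": tss,
            "strand": strand,
            "biotype": biotype,
        }
    )
    return genes.sort_values(["chrom", "tss"], ignore_index=True)


def _cis_log2_multiplier(dosage: np.ndarray, k: float) -> np.ndarray:
    """log2 of the additive-aFC expression multiplier for each dosage."""
    g = dosage.astype(float)
    return np.log2(((2.0 - g) + g * 2.0**k) / 2.0)


def make_truth(
    gt: GenotypeMatrix,
    genes: pd.DataFrame,
    tissue_names: list[str],
    seed: int = 0,
    *,
    n_cis: int = 10,
    n_trans: int = 0,
    afc_range: tuple[float, float] = (1.0, 2.0),
    cis_window: int = 1_000_000,
    shared_fraction: float = 1.0,
    trans_effect: float = 1.0,
    phasing_error_rate: float = 0.0,
    min_maf: float = 0.1,
) -> SyntheticTruth:
    """Plant cis effects (and optional mediated trans chains) at random.

    Each cis effect picks an eligible gene and a variant within
    ``cis_window`` of its TSS with MAF >= ``min_maf``; its |log2 aFC| is
    drawn from ``afc_range`` with random sign.  With probability
    ``shared_fraction`` an effect is active in every tissue, otherwise in a
    random nonempty subset.  Trans chains reuse ``n_trans`` of the cis
    effects as mediators and point them at target genes on other
    chromosomes.
    """
    if n_trans > n_cis:
        raise ValueError("every trans effect needs a mediator cis effect")
    rng = np.random.default_rng(seed)
    v = gt.variants
    usable = genes.copy()
    cis_rows = []
    chosen_genes: list[str] = []
    order = rng.permutation(len(usable))
    for gi in order:
        if len(cis_rows) == n_cis:
            break
        row = usable.iloc[gi]
        near = v[
            (v["chrom"] == row["chrom"])
            & ((v["pos"] - row["tss"]).abs() <= cis_window)
            & (v["maf"] >= min_maf)
        ]
        if near.empty:
            continue
        var = near.iloc[int(rng.integers(len(near)))]
        k = float(rng.uniform(*afc_range)) * (1 if rng.random() < 0.5 else -1)
        if rng.random() < shared_fraction:
            tissues = tuple(tissue_names)
        else:
            m = int(rng.integers(1, len(tissue_names) + 1))
            tissues = tuple(
                sorted(rng.choice(tissue_names, size=m, replace=False))
            )
        cis_rows.append(
            {
                "gene": row["gene"],
                "variant": var["variant"],
                "log2_afc": k,
                "tissues": tissues,
            }
        )
        chosen_genes.append(row["gene"])
    if len(cis_rows) < n_cis:
        raise ValueError(
            "could not place all requested cis effects; "
            "increase variant density or relax min_maf"
        )
    cis_df = pd.DataFrame(cis_rows)

    trans_rows = []
    if n_trans:
        mediators = cis_df.sample(n=n_trans, random_state=int(rng.integers(2**31)))
        free = genes[~genes["gene"].isin(chosen_genes)]
        for _, med in mediators.iterrows():
            med_chrom = genes.set_index("gene").loc[med["gene"], "chrom"]
            var_chrom = v.set_index("variant").loc[med["variant"], "chrom"]
            far = free[~free["chrom"].isin([med_chrom, var_chrom])]
            if far.empty:
                raise ValueError("no cross-chromosome target genes available")
            target = far.iloc[int(rng.integers(len(far)))]
            free = free[free["gene"] != target["gene"]]
            trans_rows.append(
                {
                    "variant": med["variant"],
                    "mediator_gene": med["gene"],
                    "target_gene": target["gene"],
                    "tissues": med["tissues"],
                    "effect": trans_effect,
                }
            )
    trans_df = pd.DataFrame(
        trans_rows,
        columns=["variant", "mediator_gene", "target_gene", "tissues", "effect"],
    )
    truth = SyntheticTruth(
        cis_effects=cis_df,
        trans_effects=trans_df,
        phasing_error_rate=phasing_error_rate,
    )
    truth.validate()
    return truth


def simulate_multitissue_expression(
    gt: GenotypeMatrix,
    n_tissues: int,
    donors_per_tissue: int,
    truth: SyntheticTruth,
    noise_sd: float = 0.5,
    n_latent: int = 0,
    seed: int = 0,
    *,
    genes: pd.DataFrame,
    tissue_names: list[str] | None = None,
    base_log2_mean: float = 3.0,
    base_log2_sd: float = 1.5,
    latent_loading_sd: float = 0.3,
    count_depth: float = 10.0,
) -> list[TissueExpression]:
    """Generate per-tissue expression with planted cis/trans effects.

    Expression is built on the log2 scale: a gene baseline, plus the
    additive-aFC cis term ``log2(((2-g) + g*2**k)/2)`` for donors of
    dosage ``g``, plus a linear trans contribution from the standardized
    log-expression of the mediator gene, plus ``n_latent`` shared latent
    factors, plus Gaussian noise of sd ``noise_sd`` (log-normal
    multiplicative noise on the natural scale).  Tissues draw overlapping
    donor subsets from the genotyped cohort.
    """
    _check_positive(n_tissues=n_tissues, donors_per_tissue=donors_per_tissue)
    if donors_per_tissue > gt.n_donors:
        raise ValueError("donors_per_tissue exceeds the genotyped cohort")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    tissue_names = tissue_names or [f"T{i}" for i in range(n_tissues)]
    if len(tissue_names) != n_tissues:
        raise ValueError("tissue_names length must equal n_tissues")
    gene_ids = genes["gene"].tolist()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    var_ids = set(gt.variants["variant"])
    for df, gcol, label in (
        (truth.cis_effects, "gene", "cis"),
        (truth.trans_effects, "mediator_gene", "trans mediator"),
        (truth.trans_effects, "target_gene", "trans target"),
    ):
        if len(df) and not df[gcol].isin(gene_pos).all():
            raise ValueError(f"truth references unknown {label} gene")
    if len(truth.cis_effects) and not truth.cis_effects["variant"].isin(
        var_ids
    ).all():
        raise ValueError("truth references unknown variant")

    rng = np.random.default_rng(seed)
    n_genes = len(gene_ids)
    baseline = rng.normal(base_log2_mean, base_log2_sd, size=n_genes)
    if n_latent:
        if truth.confounder_loadings is not None:
            loadings = truth.confounder_loadings
            if loadings.shape != (n_genes, n_latent):
                raise ValueError("confounder_loadings shape mismatch")
        else:
            loadings = rng.normal(0.0, latent_loading_sd, size=(n_genes, n_latent))
            truth.confounder_loadings = loadings

    out: list[TissueExpression] = []
    donor_arr = np.array(gt.donors)
    for t_idx, tissue in enumerate(tissue_names):
        sel = np.sort(
            rng.choice(gt.n_donors, size=donors_per_tissue, replace=False)
        )
        tissue_donors = donor_arr[sel]
        n_s = donors_per_tissue
        log2e = np.tile(baseline[:, None], (1, n_s))
        for _, eff in truth.cis_effects.iterrows():
            if tissue not in eff["tissues"]:
                continue
            vi = gt.variant_index(eff["variant"])
            g = gt.dosage[sel, vi]
            log2e[gene_pos[eff["gene"]], :] += _cis_log2_multiplier(
                g, eff["log2_afc"]
            )
        if n_latent:
            factors = rng.normal(0.0, 1.0, size=(n_latent, n_s))
            log2e += loadings @ factors
        if noise_sd > 0:
            log2e += rng.normal(0.0, noise_sd, size=log2e.shape)
        # Trans contributions use the mediator's realized (noisy)
        # log-expression, standardized within the tissue.
        for _, eff in truth.trans_effects.iterrows():
            if tissue not in eff["tissues"]:
                continue
            med = log2e[gene_pos[eff["mediator_gene"]], :]
            med_std = (med - med.mean()) / (med.std() + 1e-12)
            log2e[gene_pos[eff["target_gene"]], :] += eff["effect"] * med_std
        values = np.power(2.0, log2e)
        read_counts = rng.poisson(values * count_depth)
        samples = [f"{tissue}-{d}" for d in tissue_donors]
        out.append(
            TissueExpression(
                tissue=tissue,
                values=values,
                read_counts=read_counts,
                genes=genes.reset_index(drop=True),
                samples=samples,
                sample_to_donor=dict(zip(samples, tissue_donors)),
            )
        )
    return out


def simulate_ase_counts(
    gt: GenotypeMatrix,
    truth: SyntheticTruth,
    mean_depth: float = 50.0,
    seed: int = 0,
    *,
    genes: pd.DataFrame,
    tissue_names: list[str] | None = None,
    n_sites_per_gene: int = 2,
    nb_dispersion: float = 5.0,
    site_maf_range: tuple[float, float] = (0.2, 0.5),
    flag_fraction: float = 0.0,
) -> pd.DataFrame:
    """Allele-specific read counts at heterozygous transcribed sites.

    For every gene, ``n_sites_per_gene`` transcribed marker SNPs are
    simulated with independent haplotypes.  A donor heterozygous at a
    marker site contributes one row per tissue with depth drawn from a
    negative binomial around ``mean_depth``.  If the donor is also
    heterozygous for a planted cis eVariant of the gene with log2 aFC
    ``k`` (active in that tissue), the haplotype carrying the eVariant
    alternate allele captures a read fraction ``2**k / (1 + 2**k)``;
    otherwise both haplotypes are balanced.  The recorded haplotype
    assignment of the marker's alternate allele is flipped with the
    truth's phasing-error rate; the error-free assignment is kept in the
    ``true_hap`` column for validation.

    Returns a DataFrame with columns: donor, tissue, gene, site,
    ref_count, alt_count, hap_assignment, true_hap, total, plus boolean
    flag columns (low_mappability, mapping_bias, genotype_suspect).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if gt.hap1 is None or gt.hap2 is None:
        raise ValueError("genotypes must carry phased haplotypes")
    rng = np.random.default_rng(seed)
    tissue_names = tissue_names or ["T0"]
    eps = truth.phasing_error_rate
    cis_by_gene = {
        row["gene"]: row for _, row in truth.cis_effects.iterrows()
    }
    # Negative-binomial parameterization: size r, success prob r/(r+mu).
    r = nb_dispersion
    p_nb = r / (r + mean_depth)

    rows: list[dict] = []
    for _, grow in genes.iterrows():
        gene = grow["gene"]
        eff = cis_by_gene.get(gene)
        evar_idx = gt.variant_index(eff["variant"]) if eff is not None else None
        for s_idx in range(n_sites_per_gene):
            q = rng.uniform(*site_maf_range)
            m1 = rng.random(gt.n_donors) < q
            m2 = rng.random(gt.n_donors) < q
            het = m1 != m2  # exactly one haplotype carries the site alt
            alt_on_hap1 = m1  # site alt allele rides haplotype 1
            site = f"{gene}_s{s_idx}"
            for d_idx in np.flatnonzero(het):
                donor = gt.donors[d_idx]
                for tissue in tissue_names:
                    if eff is not None and tissue in eff["tissues"]:
                        h1a = gt.hap1[d_idx, evar_idx]
                        h2a = gt.hap2[d_idx, evar_idx]
                        w1 = 2.0 ** (eff["log2_afc"] * h1a)
                        w2 = 2.0 ** (eff["log2_afc"] * h2a)
                        hap1_frac = w1 / (w1 + w2)
                    else:
                        hap1_frac = 0.5
                    alt_frac = (
                        hap1_frac if alt_on_hap1[d_idx] else 1.0 - hap1_frac
                    )
                    depth = rng.negative_binomial(r, p_nb)
                    alt = rng.binomial(depth, alt_frac) if depth else 0
                    true_hap = "A" if alt_on_hap1[d_idx] else "B"
                    if eps and rng.random() < eps:
                        obs_hap = "B" if true_hap == "A" else "A"
                    else:
                        obs_hap = true_hap
                    rows.append(
                        {
                            "donor": donor,
                            "tissue": tissue,
                            "gene": gene,
                            "site": site,
                            "ref_count": int(depth - alt),
                            "alt_count": int(alt),
                            "hap_assignment": obs_hap,
                            "true_hap": true_hap,
                        }
                    )
    df = pd.DataFrame(
        rows,
        columns=[
            "donor",
            "tissue",
            "gene",
            "site",
            "ref_count",
            "alt_count",
            "hap_assignment",
            "true_hap",
        ],
    )
    df["total"] = df["ref_count"] + df["alt_count"]
    n = len(df)
    for flag in ("low_mappability", "mapping_bias", "genotype_suspect"):
        if flag_fraction > 0 and n:
            df[flag] = rng.random(n) < flag_fraction
        else:
            df[flag] = False
    return df


def simulate_annotations(
    gt: GenotypeMatrix,
    genes: pd.DataFrame,
    pirna_fraction: float = 0.025,
    seed: int = 0,
    *,
    genome: dict[str, int] | None = None,
    cluster_mean_length: int = 20_000,
    excluded_fraction: float = 0.05,
    n_cell_types: int = 3,
    state_window: int = 50_000,
    n_gwas_hits: int = 20,
) -> AnnotationTracks:
    """Random annotation tracks over the simulated genome.

    piRNA-like clusters are placed uniformly (outside excluded regions)
    until they cover approximately ``pirna_fraction`` of the genome; a
    centromere-like excluded region sits mid-chromosome; chromatin states
    tile the genome per simulated cell type; a small GWAS catalog samples
    genotyped variants with log-uniform p-values.
    """
    if not 0.0 <= pirna_fraction < 1.0:
        raise ValueError("pirna_fraction must lie in [0, 1)")
    genome = dict(genome or DEFAULT_GENOME)
    rng = np.random.default_rng(seed)

    excluded_rows = []
    for chrom, length in genome.items():
        half = int(length * excluded_fraction / 2)
        mid = length // 2
        excluded_rows.append(
            {"chrom": chrom, "start": mid - half, "end": mid + half,
             "label": "centromere"}
        )
    excluded = pd.DataFrame(excluded_rows)

    pirna_rows = []
    if pirna_fraction > 0:
        total_len = sum(genome.values())
        target = pirna_fraction * total_len
        covered = 0.0
        attempts = 0
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
        for chrom, length in genome.items():
            occupied[chrom].append(
                (int(excluded.loc[excluded["chrom"] == chrom, "start"].iloc[0]),
                 int(excluded.loc[excluded["chrom"] == chrom, "end"].iloc[0]))
            )
        while covered < target and attempts < 100_000:
            attempts += 1
            chrom = list(genome)[int(rng.integers(len(genome)))]
            clen = max(1000, int(rng.exponential(cluster_mean_length)))
            if clen >= genome[chrom]:
                continue
            start = int(rng.integers(0, genome[chrom] - clen))
            end = start + clen
            if any(start < e and s < end for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            pirna_rows.append(
                {"chrom": chrom, "start": start, "end": end, "label": "piRNA"}
            )
            covered += clen
    pirna = pd.DataFrame(
        pirna_rows, columns=["chrom", "start", "end", "label"]
    )

    state_labels = [
        "TssA", "Enh", "Tx", "ReprPC", "Quies",
    ]
    state_rows = []
    for ct in range(n_cell_types):
        for chrom, length in genome.items():
            starts = np.arange(0, length, state_window)
            labels = rng.choice(state_labels, size=len(starts))
            for s, lab in zip(starts, labels):
                state_rows.append(
                    {
                        "chrom": chrom,
                        "start": int(s),
                        "end": int(min(s + state_window, length)),
                        "label": f"CT{ct}:{lab}",
                    }
                )
    states = pd.DataFrame(state_rows)

    n_hits = min(n_gwas_hits, gt.n_variants)
    hit_idx = rng.choice(gt.n_variants, size=n_hits, replace=False)
    gwas = pd.DataFrame(
        {
            "variant": gt.variants["variant"].to_numpy()[hit_idx],
            "trait": [f"trait{int(rng.integers(5))}" for _ in range(n_hits)],
            "p": 10.0 ** rng.uniform(-12, -5, size=n_hits),
        }
    )

    def _sorted(df: pd.DataFrame) -> pd.DataFrame:
        return df.sort_values(["chrom", "start"], ignore_index=True)

    tracks = AnnotationTracks(
        tracks={
            "pirna": _sorted(pirna),
            "excluded": _sorted(excluded),
            "chromatin_state": _sorted(states),
        },
        gwas_catalog=gwas,
    )
    tracks.validate()
    return tracks
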