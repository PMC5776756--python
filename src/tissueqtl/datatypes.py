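"""Core in-memory containers shared by all pipeline stages.

Matrices are plain numpy arrays with pandas metadata tables alongside;
record-level results (associations, ASE calls, enrichments) are pandas
DataFrames with documented column contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column contract for association records produced by the nominal scans.
EQTL_RECORD_COLUMNS = ["gene", "variant", "tissue", "beta", "se", "t", "p_nominal"]


@dataclass
class GenotypeMatrix:
    """Hard-call alternate-allele dosages for a donor cohort.

    Attributes
    ----------
    dosage : (n_donors, n_variants) int array with values in {0, 1, 2}.
    variants : DataFrame with columns ``variant`` (id), ``chrom``, ``pos``
        (1-based), ``ref``, ``alt`` and ``maf``.
    donors : list of donor identifiers, one per dosage row.
    hap1, hap2 : optional (n_donors, n_variants) 0/1 arrays giving the
        phased alternate-allele indicator per haplotype; ``dosage`` equals
        their sum when present.  Needed by the ASE simulator.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    donors: list[str]
    hap1: np.ndarray | None = None
    hap2: np.ndarray | None = None

    @property
    def n_donors(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"unknown variant {variant_id!r}")
        return int(idx[0])

    def empirical_maf(self) -> np.ndarray:
        """Minor-allele frequency observed in the dosage matrix."""
        af = self.dosage.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def validate(self) -> None:
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (donors x variants)")
        if len(self.donors) != self.dosage.shape[0]:
            raise ValueError("donor list does not match dosage rows")
        if len(self.variants) != self.dosage.shape[1]:
            raise ValueError("variant table does not match dosage columns")
        if not np.isin(self.dosage, [0, 1, 2]).all():
            raise ValueError("hard-call dosages must lie in {0,1,2}")
        dup = self.variants.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate (chrom,pos) in variant table")


@dataclass
class TissueExpression:
    """Expression for one tissue: genes x samples, RPKM-like units.

    ``values`` holds nonnegative abundance estimates, ``read_counts`` the
    matching integer read counts used by the expression filter.  Each sample
    column maps to exactly one donor via ``sample_to_donor``.
    """

    tissue: str
    values: np.ndarray
    read_counts: np.ndarray
    genes: pd.DataFrame  # columns: gene, chrom, tss, strand, biotype
    samples: list[str]
    sample_to_donor: dict[str, str]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def donors(self) -> list[str]:
        return [self.sample_to_donor[s] for s in self.samples]

    def validate(self) -> None:
        if self.values.shape != self.read_counts.shape:
            raise ValueError("values and read_counts shapes differ")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if len(self.genes) != self.values.shape[0]:
            raise ValueError("gene table does not match value rows")
        if self.genes["gene"].duplicated().any():
            raise ValueError("gene ids must be unique")
        missing = [s for s in self.samples if s not in self.sample_to_donor]
        if missing:
            raise ValueError(f"samples without donor mapping: {missing[:3]}")


@dataclass
class SyntheticTruth:
    """Planted effects backing recovery tests.

    cis_effects : DataFrame(gene, variant, log2_afc, tissues) where
        ``tissues`` is a tuple of tissue names the effect is active in.
    trans_effects : DataFrame(variant, mediator_gene, target_gene, tissues,
        effect) — each mediator must carry a cis effect at the same variant.
    confounder_loadings : optional (n_genes, K) array of latent loadings.
    phasing_error_rate : probability a recorded haplotype assignment is
        flipped relative to truth, in [0, 0.5].
    """

    cis_effects: pd.DataFrame
    trans_effects: pd.DataFrame
    confounder_loadings: np.ndarray | None = None
    phasing_error_rate: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.phasing_error_rate <= 0.5:
            raise ValueError("phasing_error_rate must lie in [0, 0.5]")
        if len(self.cis_effects) and not np.isfinite(
            self.cis_effects["log2_afc"].to_numpy(float)
        ).all():
            raise ValueError("log2 aFC values must be finite")
        if len(self.trans_effects):
            cis_pairs = set(
                zip(self.cis_effects["gene"], self.cis_effects["variant"])
            )
            for _, row in self.trans_effects.iterrows():
                if (row["mediator_gene"], row["variant"]) not in cis_pairs:
                    raise ValueError(
                        "trans effect mediator "
                        f"{row['mediator_gene']} lacks a cis effect at "
                        f"{row['variant']}"
                    )


@dataclass
class AnnotationTracks:
    """Interval annotations (BED convention: 0-based, half-open).

    ``tracks`` maps a track name (e.g. ``pirna``, ``excluded``,
    ``chromatin_state``) to a DataFrame with columns ``chrom``, ``start``,
    ``end`` and ``label``, sorted within chromosome.
    """

    tracks: dict[str, pd.DataFrame] = field(default_factory=dict)
    gwas_catalog: pd.DataFrame | None = None  # columns: variant, trait, p

    def validate(self) -> None:
        for name, df in self.tracks.items():
            if (df["start"] >= df["end"]).any():
                raise ValueError(f"track {name!r} has empty/negative intervals")
            for _, sub in df.groupby("chrom"):
                if not sub["start"].is_monotonic_increasing:
                    raise ValueError(f"track {name!r} not sorted within chromosome")

    def track(self, name: str) -> pd.DataFrame:
        return self.tracks[name]
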