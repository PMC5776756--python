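"""Readers and writers for the on-disk formats.

Genotypes travel as VCF 4.1 with GT fields; expression as genes x samples
TSV with a header row of sample ids plus a parallel read-count TSV;
interval tracks as BED (0-based, half-open); truth and result tables as
TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from tissueqtl.datatypes import AnnotationTracks, GenotypeMatrix, TissueExpression

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}
_PHASED_CODES = {(0, 0): "0|0", (0, 1): "0|1", (1, 0): "1|0", (1, 1): "1|1"}


def write_vcf(gt: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as VCF 4.1 (phased GT when haplotypes exist)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = gt.variants["chrom"].unique()
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.donors)
            + "\n"
        )
        phased = gt.hap1 is not None and gt.hap2 is not None
        for j, row in gt.variants.iterrows():
            if phased:
                calls = [
                    _PHASED_CODES[(int(gt.hap1[i, j]), int(gt.hap2[i, j]))]
                    for i in range(gt.n_donors)
                ]
            else:
                calls = [_GT_CODES[int(gt.dosage[i, j])] for i in range(gt.n_donors)]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (plain-text) VCF with GT fields into a GenotypeMatrix."""
    path = Path(path)
    donors: list[str] = []
    chroms: list[str] = []
    pos: list[int] = []
    ids: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    h1_rows: list[list[int]] = []
    h2_rows: list[list[int]] = []
    phased = True
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                donors = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chroms.append(fields[0])
            pos.append(int(fields[1]))
            ids.append(fields[2])
            refs.append(fields[3])
            alts.append(fields[4])
            fmt = fields[8].split(":")
            gti = fmt.index("GT")
            a1s, a2s = [], []
            for call in fields[9:]:
                gtf = call.split(":")[gti]
                sep = "|" if "|" in gtf else "/"
                if sep == "/":
                    phased = False
                a1, a2 = (int(x) for x in gtf.split(sep))
                a1s.append(a1)
                a2s.append(a2)
            h1_rows.append(a1s)
            h2_rows.append(a2s)
    hap1 = np.array(h1_rows, dtype=np.int8).T
    hap2 = np.array(h2_rows, dtype=np.int8).T
    dosage = hap1 + hap2
    af = dosage.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "variant": ids, "chrom": chroms, "pos": pos,
            "ref": refs, "alt": alts,
            "maf": np.minimum(af, 1 - af),
        }
    )
    return GenotypeMatrix(
        dosage=dosage, variants=variants, donors=donors,
        hap1=hap1 if phased else None, hap2=hap2 if phased else None,
    )


def write_expression_tsv(expr: TissueExpression, prefix: str | Path) -> None:
    """Write values and read counts as genes x samples TSVs.

    ``<prefix>.rpkm.tsv`` and ``<prefix>.reads.tsv``; first column is the
    gene id, the header row holds sample ids.  Gene metadata goes to
    ``<prefix>.genes.tsv`` and the sample-donor map to
    ``<prefix>.samples.tsv``.
    """
    prefix = Path(prefix)
    values = pd.DataFrame(
        expr.values, index=expr.genes["gene"], columns=expr.samples
    )
    counts = pd.DataFrame(
        expr.read_counts, index=expr.genes["gene"], columns=expr.samples
    )
    values.to_csv(f"{prefix}.rpkm.tsv", sep="\t", index_label="gene")
    counts.to_csv(f"{prefix}.reads.tsv", sep="\t", index_label="gene")
    expr.genes.to_csv(f"{prefix}.genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "sample": expr.samples,
            "donor": [expr.sample_to_donor[s] for s in expr.samples],
        }
    ).to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)


def read_expression_tsv(prefix: str | Path, tissue: str) -> TissueExpression:
    prefix = Path(prefix)
    values = pd.read_csv(f"{prefix}.rpkm.tsv", sep="\t", index_col="gene")
    counts = pd.read_csv(f"{prefix}.reads.tsv", sep="\t", index_col="gene")
    genes = pd.read_csv(f"{prefix}.genes.tsv", sep="\t")
    samples_df = pd.read_csv(f"{prefix}.samples.tsv", sep="\t")
    return TissueExpression(
        tissue=tissue,
        values=values.to_numpy(float),
        read_counts=counts.to_numpy(int),
        genes=genes,
        samples=list(values.columns),
        sample_to_donor=dict(zip(samples_df["sample"], samples_df["donor"])),
    )


def write_bed(track: pd.DataFrame, path: str | Path) -> None:
    """Write a track as BED (0-based, half-open), with optional name."""
    cols = ["chrom", "start", "end"]
    if "label" in track.columns:
        cols.append("label")
    track[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "label"],
        usecols=[0, 1, 2, 3] if _bed_has_name(path) else [0, 1, 2],
    )
    if "label" not in df.columns:
        df["label"] = "."
    return df.sort_values(["chrom", "start"], ignore_index=True)


def _bed_has_name(path: str | Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return len(first.rstrip("\n").split("\t")) >= 4


def write_annotations(tracks: AnnotationTracks, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tracks.tracks.items():
        write_bed(df, outdir / f"{name}.bed")
    if tracks.gwas_catalog is not None:
        tracks.gwas_catalog.to_csv(
            outdir / "gwas_catalog.tsv", sep="\t", index=False
        )


def write_truth(truth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cis = truth.cis_effects.copy()
    cis["tissues"] = cis["tissues"].map(lambda t: ",".join(t))
    cis.to_csv(outdir / "truth_cis.tsv", sep="\t", index=False)
    trans = truth.trans_effects.copy()
    if len(trans):
        trans["tissues"] = trans["tissues"].map(lambda t: ",".join(t))
    trans.to_csv(outdir / "truth_trans.tsv", sep="\t", index=False)
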