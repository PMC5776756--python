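"""End-to-end orchestration: synthetic study -> mapping -> evaluation.

A single declarative config drives simulation, preprocessing, cis and
trans mapping, cross-tissue meta-analysis and truth evaluation.  Every
random stage consumes a seed derived deterministically from the master
seed and the stage name, so re-running an identical config reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tissueqtl import io as tio
from tissueqtl import synthetic
from tissueqtl.cis import map_cis_tissue
from tissueqtl.datatypes import GenotypeMatrix, SyntheticTruth
from tissueqtl.multi_tissue import meta_analyze_pairs, sharing_summary
from tissueqtl.preprocess import preprocess_tissue
from tissueqtl.trans import TransScanConfig, bh_fdr, trans_scan

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "tissueqtl_run"
    n_donors: int = 120
    n_variants: int = 400
    n_genes: int = 300
    n_tissues: int = 5
    donors_per_tissue: int = 100
    n_cis: int = 20
    n_trans: int = 2
    afc_range: tuple[float, float] = (1.0, 2.0)
    noise_sd: float = 0.5
    n_latent_truth: int = 2
    ld_block_size: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    latent_k: int | None = 5
    cis_fdr: float = 0.05
    cis_window: int = 1_000_000
    perm_min: int = 1_000
    perm_max: int = 10_000
    trans_fdr: float = 0.10
    stages: tuple[str, ...] = ("simulate", "preprocess", "cis", "trans",
                               "meta", "evaluate")
    run_stepwise: bool = False
    write_outputs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("afc_range", "maf_range", "stages"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


_STAGE_ORDER = ["simulate", "preprocess", "cis", "trans", "meta", "evaluate"]
_STAGE_DEPS = {
    "preprocess": ["simulate"],
    "cis": ["preprocess"],
    "trans": ["preprocess"],
    "meta": ["cis"],
    "evaluate": ["cis"],
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a dict of in-memory artifacts; when ``cfg.write_outputs`` is
    set, TSV outputs and a manifest land under ``cfg.outdir``.
    """
    enabled = [s for s in _STAGE_ORDER if s in cfg.stages]
    for stage in enabled:
        for dep in _STAGE_DEPS.get(stage, []):
            if dep not in enabled:
                raise ValueError(
                    f"stage {stage!r} requires {dep!r}, which is disabled"
                )
    outdir = Path(cfg.outdir)
    if cfg.write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"config": cfg}
    timings: dict[str, float] = {}

    def _log(stage: str, start: float, **counts) -> None:
        timings[stage] = time.perf_counter() - start
        logger.info("stage %s done in %.1fs %s", stage, timings[stage], counts)

    if "simulate" in enabled:
        t0 = time.perf_counter()
        seed = stage_seed(cfg.seed, "simulate")
        gt = synthetic.simulate_genotypes(
            cfg.n_donors, cfg.n_variants, cfg.maf_range,
            cfg.ld_block_size, seed,
        )
        genes = synthetic.simulate_gene_table(cfg.n_genes, seed + 1)
        tissue_names = [f"T{i}" for i in range(cfg.n_tissues)]
        truth = synthetic.make_truth(
            gt, genes, tissue_names, seed + 2,
            n_cis=cfg.n_cis, n_trans=cfg.n_trans, afc_range=cfg.afc_range,
        )
        tissues = synthetic.simulate_multitissue_expression(
            gt, cfg.n_tissues, cfg.donors_per_tissue, truth,
            noise_sd=cfg.noise_sd, n_latent=cfg.n_latent_truth,
            seed=seed + 3, genes=genes, tissue_names=tissue_names,
        )
        artifacts.update(gt=gt, genes=genes, truth=truth, tissues=tissues)
        if cfg.write_outputs:
            tio.write_vcf(gt, outdir / "genotypes.vcf")
            tio.write_truth(truth, outdir)
            for te in tissues:
                tio.write_expression_tsv(te, outdir / f"expr_{te.tissue}")
        _log("simulate", t0, donors=gt.n_donors, variants=gt.n_variants)

    if "preprocess" in enabled:
        t0 = time.perf_counter()
        norm, cov = {}, {}
        for te in artifacts["tissues"]:
            norm[te.tissue], cov[te.tissue] = preprocess_tissue(
                te, k=cfg.latent_k
            )
        artifacts.update(norm=norm, cov=cov)
        _log("preprocess", t0, tissues=len(norm))

    if "cis" in enabled:
        t0 = time.perf_counter()
        cis_results = {}
        for tissue, nrm in artifacts["norm"].items():
            cis_results[tissue] = map_cis_tissue(
                nrm, artifacts["cov"][tissue], artifacts["gt"],
                window=cfg.cis_window, fdr=cfg.cis_fdr,
                n_min=cfg.perm_min, n_max=cfg.perm_max,
                seed=stage_seed(cfg.seed, f"cis:{tissue}"),
                run_stepwise=cfg.run_stepwise,
            )
        artifacts["cis"] = cis_results
        if cfg.write_outputs:
            for tissue, res in cis_results.items():
                res["egenes"].to_csv(
                    outdir / f"egenes_{tissue}.tsv", sep="\t", index=False
                )
                res["signif_pairs"].to_csv(
                    outdir / f"signif_pairs_{tissue}.tsv", sep="\t", index=False
                )
        _log("cis", t0, genes=sum(len(r["egenes"]) for r in cis_results.values()))

    if "trans" in enabled:
        t0 = time.perf_counter()
        trans_results = {}
        for tissue, nrm in artifacts["norm"].items():
            records = trans_scan(
                artifacts["gt"], nrm, artifacts["cov"][tissue],
                TransScanConfig(fdr=cfg.trans_fdr),
            )
            trans_results[tissue] = {
                "pairs": records,
                "signif": bh_fdr(records, cfg.trans_fdr),
            }
        artifacts["trans"] = trans_results
        if cfg.write_outputs:
            for tissue, res in trans_results.items():
                res["signif"].to_csv(
                    outdir / f"trans_signif_{tissue}.tsv", sep="\t", index=False
                )
        _log("trans", t0,
             signif=sum(len(r["signif"]) for r in trans_results.values()))

    if "meta" in enabled:
        t0 = time.perf_counter()
        frames = []
        for tissue, res in artifacts["cis"].items():
            eg = res["egenes"]
            if eg.empty:
                continue
            frames.append(
                eg[["gene", "top_variant", "beta", "se"]]
                .rename(columns={"top_variant": "variant"})
                .assign(tissue=tissue)
            )
        effects = (
            pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        )
        meta = (
            meta_analyze_pairs(effects) if len(effects) else pd.DataFrame()
        )
        artifacts["meta"] = meta
        if len(effects):
            artifacts["sharing"] = sharing_summary(effects, meta)
        if cfg.write_outputs and len(meta):
            meta.to_csv(outdir / "meta_results.tsv", sep="\t", index=False)
            sh = artifacts.get("sharing")
            if sh and sh.get("newick"):
                (outdir / "dendrogram.nwk").write_text(sh["newick"] + "\n")
        _log("meta", t0, pairs=len(meta))

    if "evaluate" in enabled:
        t0 = time.perf_counter()
        report = evaluate_against_truth(artifacts, artifacts["truth"])
        artifacts["truth_report"] = report
        if cfg.write_outputs:
            report.to_csv(outdir / "truth_report.tsv", sep="\t", index=False)
        _log("evaluate", t0)

    if cfg.write_outputs:
        manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
            "stages": enabled,
            "stage_seconds": {k: round(v, 2) for k, v in timings.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return artifacts


def _ld_r2(gt: GenotypeMatrix, v1: str, v2: str) -> float:
    i, j = gt.variant_index(v1), gt.variant_index(v2)
    a = gt.dosage[:, i].astype(float)
    b = gt.dosage[:, j].astype(float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def evaluate_against_truth(
    artifacts: dict,
    truth: SyntheticTruth,
    r2_match: float = 0.8,
) -> pd.DataFrame:
    """Recall / FDR per discovery category versus the planted truth.

    A discovery counts as true when its variant has r^2 >= ``r2_match``
    with a planted variant for the same gene.
    """
    gt: GenotypeMatrix = artifacts["gt"]
    rows = []

    planted_cis = {
        row["gene"]: row for _, row in truth.cis_effects.iterrows()
    }
    if "cis" in artifacts:
        found_genes: set[str] = set()
        false_genes: set[str] = set()
        for tissue, res in artifacts["cis"].items():
            eg = res["egenes"]
            if eg.empty or "egene" not in eg.columns:
                continue
            for _, row in eg[eg["egene"]].iterrows():
                planted = planted_cis.get(row["gene"])
                if planted is not None and (
                    row["top_variant"] == planted["variant"]
                    or _ld_r2(gt, row["top_variant"], planted["variant"])
                    >= r2_match
                ):
                    found_genes.add(row["gene"])
                else:
                    false_genes.add((tissue, row["gene"]))
        n_planted = len(planted_cis)
        n_calls = len(found_genes) + len(false_genes)
        rows.append(
            {
                "category": "cis_egenes",
                "recall": len(found_genes) / n_planted if n_planted else np.nan,
                "fdr": len(false_genes) / n_calls if n_calls else 0.0,
                "n_true": len(found_genes),
                "n_false": len(false_genes),
                "n_planted": n_planted,
            }
        )

    if "trans" in artifacts and len(truth.trans_effects):
        planted_trans = {
            (row["variant"], row["target_gene"])
            for _, row in truth.trans_effects.iterrows()
        }
        hits: set = set()
        false_pairs: set = set()
        for tissue, res in artifacts["trans"].items():
            for _, row in res["signif"].iterrows():
                matched = any(
                    gene == row["gene"]
                    and (
                        var == row["variant"]
                        or _ld_r2(gt, row["variant"], var) >= r2_match
                    )
                    for var, gene in planted_trans
                )
                if matched:
                    hits.add(
                        next(
                            (v, g) for v, g in planted_trans
                            if g == row["gene"]
                        )
                    )
                else:
                    false_pairs.add((tissue, row["variant"], row["gene"]))
        n_calls = len(hits) + len(false_pairs)
        rows.append(
            {
                "category": "trans_pairs",
                "recall": len(hits) / len(planted_trans),
                "fdr": len(false_pairs) / n_calls if n_calls else 0.0,
                "n_true": len(hits),
                "n_false": len(false_pairs),
                "n_planted": len(planted_trans),
            }
        )
    return pd.DataFrame(rows)
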