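"""Shared fixtures: one compact synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from tissueqtl import synthetic as syn


@pytest.fixture(scope="session")
def small_gt():
    """150 donors x 150 variants, LD blocks of 5."""
    return syn.simulate_genotypes(150, 150, (0.1, 0.5), 5, seed=11)


@pytest.fixture(scope="session")
def small_genes():
    return syn.simulate_gene_table(30, seed=12)


@pytest.fixture(scope="session")
def small_truth(small_gt, small_genes):
    return syn.make_truth(
        small_gt, small_genes, ["T0", "T1"], seed=13, n_cis=5, n_trans=1
    )


@pytest.fixture(scope="session")
def small_tissues(small_gt, small_genes, small_truth):
    return syn.simulate_multitissue_expression(
        small_gt, 2, 120, small_truth, noise_sd=0.5, n_latent=2, seed=14,
        genes=small_genes, tissue_names=["T0", "T1"],
    )


def toy_genotypes(dosage: np.ndarray, chrom="chr1", spacing=1000):
    """Build a GenotypeMatrix from an explicit dosage matrix."""
    from tissueqtl.datatypes import GenotypeMatrix

    n_donors, n_var = dosage.shape
    pos = [spacing * (i + 1) for i in range(n_var)]
    af = dosage.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "variant": [f"v{i}" for i in range(n_var)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(af, 1 - af),
        }
    )
    return GenotypeMatrix(
        dosage=dosage.astype(np.int8),
        variants=variants,
        donors=[f"D{i:03d}" for i in range(n_donors)],
    )
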