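"""Expression filtering, normalization and covariate construction.

Per tissue: genes are kept when at least 10 donors show abundance above
0.1 (RPKM-like units) with at least 6 supporting reads; kept expression is
quantile-normalized across samples to the average empirical distribution,
then each gene is rank-transformed to the quantiles of the standard
normal; known covariates are combined with latent factors that capture
residual structured variation (one factor count chosen by the sample-size
rule 15 / 30 / 35).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tissueqtl.datatypes import TissueExpression

logger = logging.getLogger(__name__)

#: Expression filter thresholds.
MIN_RPKM = 0.1
MIN_READS = 6
MIN_DONORS = 10


@dataclass
class NormalizedExpression:
    """Inverse-normal-scored expression for kept genes (genes x samples)."""

    tissue: str
    values: np.ndarray
    kept_genes: list[str]
    genes: pd.DataFrame
    samples: list[str]
    sample_to_donor: dict[str, str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def donors(self) -> list[str]:
        return [self.sample_to_donor[s] for s in self.samples]


@dataclass
class CovariateSet:
    """Known plus inferred covariates, samples x columns."""

    known: np.ndarray
    latent: np.ndarray
    samples: list[str]
    known_names: list[str]
    k: int

    @property
    def matrix(self) -> np.ndarray:
        if self.latent.size:
            return np.hstack([self.known, self.latent])
        return self.known


def filter_expressed_genes(expr: TissueExpression) -> list[str]:
    """Gene ids passing the expression filter.

    A gene is kept iff at least ``MIN_DONORS`` *donors* (not samples)
    have abundance > ``MIN_RPKM`` and read count >= ``MIN_READS``.
    """
    if expr.read_counts is None:
        raise ValueError("read-count matrix required for the expression filter")
    donors = np.array(expr.donors)
    qualifies = (expr.values > MIN_RPKM) & (expr.read_counts >= MIN_READS)
    kept = []
    # Count distinct qualifying donors per gene (a donor with several
    # samples counts once).
    uniq, inv = np.unique(donors, return_inverse=True)
    n_donors = len(uniq)
    for gi in range(expr.n_genes):
        ok = np.zeros(n_donors, dtype=bool)
        np.logical_or.at(ok, inv, qualifies[gi])
        if ok.sum() >= MIN_DONORS:
            kept.append(expr.genes["gene"].iloc[gi])
    return kept


def quantile_normalize_samples(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns to the average empirical distribution.

    Every sample column is mapped rank-for-rank onto the across-sample
    average of order statistics, so all columns share identical sorted
    values while within-sample ranks are preserved.  Ties receive the
    average of the reference values they span.
    """
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >= 2 samples")
    if np.isnan(values).any():
        raise ValueError("NaNs in expression matrix")
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values, dtype=float)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        # Average-rank tie handling: identical inputs get the mean of the
        # reference slots they occupy.
        ranks = stats.rankdata(col, method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[np.minimum(hi, n - 1)])
    return out


def inverse_normal_transform(row: np.ndarray) -> np.ndarray:
    """Map a vector to standard-normal quantiles by rank.

    Rank ``r`` (1-based, average ranks for ties) maps to
    ``Phi^{-1}(r / (n + 1))``.  A constant vector maps to all zeros.
    """
    row = np.asarray(row, dtype=float)
    n = row.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if np.all(row == row[0]):
        logger.warning("constant expression row; inverse-normal set to zeros")
        return np.zeros(n)
    ranks = stats.rankdata(row, method="average")
    return stats.norm.ppf(ranks / (n + 1.0))


def normalize_tissue(expr: TissueExpression) -> NormalizedExpression:
    """Filter, quantile-normalize and inverse-normal-score one tissue."""
    kept = filter_expressed_genes(expr)
    keep_mask = expr.genes["gene"].isin(kept).to_numpy()
    vals = expr.values[keep_mask]
    qn = quantile_normalize_samples(vals)
    scores = np.vstack([inverse_normal_transform(r) for r in qn])
    return NormalizedExpression(
        tissue=expr.tissue,
        values=scores,
        kept_genes=list(expr.genes["gene"][keep_mask]),
        genes=expr.genes[keep_mask].reset_index(drop=True),
        samples=list(expr.samples),
        sample_to_donor=dict(expr.sample_to_donor),
    )


def choose_latent_k(n_samples: int, override: int | None = None) -> int:
    """Latent-factor count by the sample-size rule (15 / 30 / 35)."""
    if override is not None:
        return override
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if n_samples < 150:
        return 15
    if n_samples <= 250:
        return 30
    return 35


def infer_latent_factors(
    norm: NormalizedExpression,
    k: int,
    known: np.ndarray | None = None,
    known_names: list[str] | None = None,
) -> CovariateSet:
    """Latent covariates as top residual-variance directions.

    Known covariates (plus an intercept) are projected out of the
    normalized matrix; the leading ``k`` right singular vectors of the
    residual (samples x genes) become the latent factors.  Deterministic
    sign convention: the largest-|loading| entry of each factor is
    positive.
    """
    n_samples = norm.n_samples
    if k >= n_samples:
        raise ValueError("k must be smaller than the sample count")
    if known is None:
        known = np.ones((n_samples, 1))
        known_names = ["intercept"]
    else:
        known = np.asarray(known, dtype=float)
        if known.shape[0] != n_samples:
            raise ValueError("known covariates rows must match samples")
        if not np.allclose(known.std(axis=0), 0.0).any():
            known = np.hstack([np.ones((n_samples, 1)), known])
            known_names = ["intercept"] + list(
                known_names or [f"known{i}" for i in range(known.shape[1] - 1)]
            )
    if np.linalg.matrix_rank(known) < known.shape[1]:
        raise ValueError("known covariates are collinear")

    x = norm.values.T  # samples x genes
    q, _ = np.linalg.qr(known)
    resid = x - q @ (q.T @ x)
    if k == 0:
        latent = np.empty((n_samples, 0))
    else:
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        latent = u[:, :k] * s[:k]
        for j in range(latent.shape[1]):
            i = np.argmax(np.abs(latent[:, j]))
            if latent[i, j] < 0:
                latent[:, j] = -latent[:, j]
    return CovariateSet(
        known=known,
        latent=latent,
        samples=list(norm.samples),
        known_names=list(known_names or []),
        k=k,
    )


def preprocess_tissue(
    expr: TissueExpression,
    known: np.ndarray | None = None,
    known_names: list[str] | None = None,
    k: int | None = None,
) -> tuple[NormalizedExpression, CovariateSet]:
    """Full per-tissue preprocessing: filter, normalize, covariates."""
    norm = normalize_tissue(expr)
    k_eff = choose_latent_k(norm.n_samples, override=k)
    k_eff = min(k_eff, norm.n_samples - 2, norm.values.shape[0] - 1)
    k_eff = max(k_eff, 0)
    cov = infer_latent_factors(norm, k_eff, known=known, known_names=known_names)
    return norm, cov
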