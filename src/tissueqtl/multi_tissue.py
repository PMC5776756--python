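"""Cross-tissue meta-analysis and tissue-sharing statistics.

Per-tissue effects of a variant-gene pair are combined by
inverse-variance fixed-effects and DerSimonian-Laird random-effects
meta-analysis after a donor-overlap decorrelation step that inflates
standard errors to account for correlated measurement error in tissues
sampled from shared donors.  Per-tissue m-values (posterior probability
that the effect exists in a tissue) are computed by exact enumeration
over all effect/no-effect configurations.  Tissue sharing is summarized
by pi1 replication between tissue pairs and by hierarchical clustering
of tissues under the 1 - Spearman's rho distance on effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from tissueqtl.fdr import storey_pi0  # noqa: F401  (shared estimator)

#: m-value prior defaults: probability a tissue harbors the effect, and
#: the effect-size prior sd on the inverse-normal scale.
DEFAULT_PRIOR_PI = 0.5
DEFAULT_PRIOR_SD = 0.2
EXACT_T_CAP = 16


@dataclass
class MetaResult:
    beta_fixed: float
    se_fixed: float
    z_fixed: float
    p_fixed: float
    beta_random: float
    se_random: float
    z_random: float
    p_random: float
    tau2: float


def decorrelate_effects(
    beta: np.ndarray,
    se: np.ndarray,
    error_corr: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Inflate SEs for between-tissue error correlation from shared donors.

    ``error_corr`` is the T x T correlation of the per-tissue effect
    estimators (e.g. ``overlap_fraction * residual_correlation``); with
    zero donor overlap it is the identity and the inputs pass through.
    The inflation is uniform: all SEs scale by sqrt(lambda) where
    ``lambda = w' C w / sum(w)`` (w the inverse-variance weights, C the
    estimator covariance), so that an independent fixed-effects
    meta-analysis of the adjusted inputs has exactly the variance of the
    correlation-aware one.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    if error_corr is None:
        return beta.copy(), se.copy()
    corr = np.asarray(error_corr, dtype=float)
    t = beta.size
    if corr.shape != (t, t):
        raise ValueError("error_corr must be T x T")
    w = 1.0 / se**2
    cov = corr * np.outer(se, se)
    # Full-covariance meta variance is (w' C w) / (sum w)^2; an independent
    # meta on SEs inflated by sqrt(f) has variance f / sum(w), so
    # f = (w' C w) / sum(w) reproduces it exactly.
    inflation = max(float(w @ cov @ w) / float(w.sum()), 1.0)
    return beta.copy(), se * np.sqrt(inflation)


def overlap_error_correlation(
    n_samples: np.ndarray,
    n_shared: np.ndarray,
    residual_corr: np.ndarray | None = None,
) -> np.ndarray:
    """Estimator correlation induced by shared donors.

    corr_ij = (n_shared_ij / sqrt(n_i * n_j)) * rho_ij, where rho_ij is
    the residual expression correlation across shared donors (1.0 when
    not supplied, the conservative duplicated-measurement limit).
    """
    n_samples = np.asarray(n_samples, dtype=float)
    n_shared = np.asarray(n_shared, dtype=float)
    t = n_samples.size
    frac = n_shared / np.sqrt(np.outer(n_samples, n_samples))
    rho = np.ones((t, t)) if residual_corr is None else np.asarray(residual_corr)
    corr = frac * rho
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def meta_analyze(beta: np.ndarray, se: np.ndarray) -> MetaResult:
    """Inverse-variance fixed effects + DerSimonian-Laird random effects."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if beta.size < 1:
        raise ValueError("need at least one tissue")
    w = 1.0 / se**2
    sw = w.sum()
    b_fixed = float((w * beta).sum() / sw)
    se_fixed = float(np.sqrt(1.0 / sw))
    z_fixed = b_fixed / se_fixed
    p_fixed = 2.0 * stats.norm.sf(abs(z_fixed))

    t = beta.size
    if t > 1:
        q = float((w * (beta - b_fixed) ** 2).sum())
        c = sw - float((w**2).sum()) / sw
        tau2 = max(0.0, (q - (t - 1)) / c) if c > 0 else 0.0
    else:
        tau2 = 0.0
    w_r = 1.0 / (se**2 + tau2)
    sw_r = w_r.sum()
    b_rand = float((w_r * beta).sum() / sw_r)
    se_rand = float(np.sqrt(1.0 / sw_r))
    z_rand = b_rand / se_rand
    p_rand = 2.0 * stats.norm.sf(abs(z_rand))
    return MetaResult(
        beta_fixed=b_fixed, se_fixed=se_fixed, z_fixed=float(z_fixed),
        p_fixed=float(p_fixed), beta_random=b_rand, se_random=se_rand,
        z_random=float(z_rand), p_random=float(p_rand), tau2=float(tau2),
    )


def m_values(
    beta: np.ndarray,
    se: np.ndarray,
    prior_pi: float = DEFAULT_PRIOR_PI,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> np.ndarray:
    """Posterior probability the effect exists in each tissue.

    Exact enumeration over all 2^T effect configurations: under
    "no effect" the tissue likelihood is N(beta; 0, se^2); under
    "effect", the marginal N(beta; 0, se^2 + prior_sd^2).  Configuration
    prior is prior_pi^(#effects) * (1 - prior_pi)^(T - #effects).
    m_t is the posterior mass of configurations with tissue t active.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    t = beta.size
    if t > EXACT_T_CAP:
        raise ValueError(
            f"exact enumeration capped at T={EXACT_T_CAP}; "
            "use m_values_sampled for larger tissue counts"
        )
    if not 0.0 <= prior_pi <= 1.0:
        raise ValueError("prior_pi must lie in [0, 1]")
    from scipy.special import xlogy

    log_null = stats.norm.logpdf(beta, 0.0, se)
    log_alt = stats.norm.logpdf(beta, 0.0, np.sqrt(se**2 + prior_sd**2))
    configs = np.arange(2**t, dtype=np.int64)
    bits = (configs[:, None] >> np.arange(t)[None, :]) & 1  # (2^T, T)
    n_active = bits.sum(axis=1)
    # xlogy handles the degenerate priors 0 and 1 (0 * log 0 == 0)
    log_prior = xlogy(n_active, prior_pi) + xlogy(t - n_active, 1 - prior_pi)
    loglik = bits @ log_alt + (1 - bits) @ log_null + log_prior
    loglik -= loglik[np.isfinite(loglik)].max()
    weights = np.exp(loglik)
    weights /= weights.sum()
    return bits.T @ weights


def m_values_sampled(
    beta: np.ndarray,
    se: np.ndarray,
    prior_pi: float = DEFAULT_PRIOR_PI,
    prior_sd: float = DEFAULT_PRIOR_SD,
    n_samples: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo m-values: posterior over sampled configurations.

    Importance sampler with per-tissue independent proposal equal to the
    single-tissue posterior; serves as the cross-check for the exact
    enumeration and as the fallback above the exact tissue cap.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    t = beta.size
    rng = np.random.default_rng(seed)
    log_null = stats.norm.logpdf(beta, 0.0, se)
    log_alt = stats.norm.logpdf(beta, 0.0, np.sqrt(se**2 + prior_sd**2))
    # Single-tissue posterior as proposal
    a = prior_pi * np.exp(log_alt - np.maximum(log_alt, log_null))
    b = (1 - prior_pi) * np.exp(log_null - np.maximum(log_alt, log_null))
    prop = np.clip(a / (a + b), 0.01, 0.99)
    draws = rng.random((n_samples, t)) < prop[None, :]
    bits = draws.astype(float)
    log_w = (
        bits @ (log_alt + np.log(prior_pi) - np.log(prop))
        + (1 - bits) @ (log_null + np.log1p(-prior_pi) - np.log1p(-prop))
    )
    log_w -= log_w.max()
    w = np.exp(log_w)
    return (bits.T @ w) / w.sum()


def meta_analyze_pairs(
    effects: pd.DataFrame,
    error_corr: np.ndarray | None = None,
    tissue_order: list[str] | None = None,
    prior_pi: float = DEFAULT_PRIOR_PI,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> pd.DataFrame:
    """Meta-analysis + m-values for a table of per-tissue effects.

    ``effects`` columns: gene, variant, tissue, beta, se.  Returns one
    row per (gene, variant, tissue) with meta p and the tissue m-value.
    """
    tissue_order = tissue_order or sorted(effects["tissue"].unique())
    t_index = {t: i for i, t in enumerate(tissue_order)}
    rows = []
    for (gene, variant), grp in effects.groupby(["gene", "variant"], sort=False):
        beta = grp["beta"].to_numpy(float)
        se = grp["se"].to_numpy(float)
        sub_corr = None
        if error_corr is not None:
            sel = [t_index[t] for t in grp["tissue"]]
            sub_corr = error_corr[np.ix_(sel, sel)]
        b_adj, se_adj = decorrelate_effects(beta, se, sub_corr)
        meta = meta_analyze(b_adj, se_adj)
        m = m_values(b_adj, se_adj, prior_pi=prior_pi, prior_sd=prior_sd)
        for i, (_, row) in enumerate(grp.iterrows()):
            rows.append(
                {
                    "gene": gene,
                    "variant": variant,
                    "tissue": row["tissue"],
                    "beta": beta[i],
                    "se": se[i],
                    "se_adjusted": se_adj[i],
                    "m_value": m[i],
                    "meta_p_fixed": meta.p_fixed,
                    "meta_p_random": meta.p_random,
                }
            )
    return pd.DataFrame(rows)


def pairwise_replication(
    discovery: dict[str, pd.DataFrame],
    all_pairs: dict[str, pd.DataFrame],
    min_pairs: int = 50,
) -> pd.DataFrame:
    """pi1 replication matrix over ordered tissue pairs.

    ``discovery[tissue]`` holds that tissue's significant pairs (columns
    gene, variant); ``all_pairs[tissue]`` holds all tested pairs with
    ``p_nominal``.  pi1(A -> B) applies Storey's estimator to B's
    p-values at A's discoveries.  Pairs untestable in B are dropped; a
    low-confidence flag is set below ``min_pairs`` testable pairs.
    """
    tissues = sorted(all_pairs)
    rows = []
    indexed = {
        t: df.set_index(["gene", "variant"])["p_nominal"]
        for t, df in all_pairs.items()
    }
    for a in tissues:
        disc = discovery.get(a)
        keys = (
            list(zip(disc["gene"], disc["variant"]))
            if disc is not None and len(disc)
            else []
        )
        for b in tissues:
            pb = indexed[b]
            p_rep = pb.loc[[k for k in keys if k in pb.index]].to_numpy(float)
            if p_rep.size == 0:
                rows.append(
                    {"discovery": a, "replication": b, "pi1": np.nan,
                     "n_pairs": 0, "low_confidence": True}
                )
                continue
            pi1 = 1.0 - storey_pi0(p_rep)
            rows.append(
                {
                    "discovery": a,
                    "replication": b,
                    "pi1": pi1,
                    "n_pairs": int(p_rep.size),
                    "low_confidence": p_rep.size < min_pairs,
                }
            )
    return pd.DataFrame(rows)


def sharing_summary(
    effects: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    m_cut: float = 0.9,
) -> dict:
    """Tissue-sharing summary: rho matrix, dendrogram, m-value histogram.

    Spearman's rho of effect sizes is computed per tissue pair over the
    (gene, variant) pairs present in both; tissues are clustered by
    average-linkage agglomeration on 1 - rho.  When meta results with
    m-values are supplied, the histogram of tissues-with-m-above-cut per
    eQTL is included.
    """
    wide = effects.pivot_table(
        index=["gene", "variant"], columns="tissue", values="beta"
    )
    tissues = list(wide.columns)
    t = len(tissues)
    rho = np.ones((t, t))
    for i in range(t):
        for j in range(i + 1, t):
            sub = wide[[tissues[i], tissues[j]]].dropna()
            if len(sub) >= 3:
                r = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1]).statistic
            else:
                r = np.nan
            rho[i, j] = rho[j, i] = r
    dist = 1.0 - np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(t, k=1)]
    linkage = (
        hierarchy.linkage(condensed, method="average") if t > 1 else None
    )
    out = {
        "tissues": tissues,
        "rho": pd.DataFrame(rho, index=tissues, columns=tissues),
        "linkage": linkage,
        "newick": _linkage_to_newick(linkage, tissues) if linkage is not None else None,
    }
    if meta is not None and len(meta):
        counts = (
            meta[meta["m_value"] > m_cut]
            .groupby(["gene", "variant"])
            .size()
        )
        all_pairs = meta.groupby(["gene", "variant"]).size()
        counts = counts.reindex(all_pairs.index, fill_value=0)
        out["n_shared"] = counts
    return out


def cluster_labels(linkage: np.ndarray, n_clusters: int) -> np.ndarray:
    """Flat cluster assignment from the sharing dendrogram."""
    return hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")


def _linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def recurse(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = recurse(node.left)
        right = recurse(node.right)
        dl = max(node.dist - node.left.dist, 0.0)
        dr = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return recurse(tree) + ";"
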