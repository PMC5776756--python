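"""GWAS-eQTL colocalization and cis-to-trans Mendelian randomization.

Colocalization follows the five-hypothesis Bayesian framework: per-variant
Wakefield approximate Bayes factors for each trait are combined over the
configuration space {no signal, trait-1 only, trait-2 only, two distinct
causal variants, one shared causal variant} with priors p1, p2, p12; a
locus colocalizes when PP4 / (PP3 + PP4) > 0.9.  Mendelian randomization
treats the eVariant as an instrument for the cis-gene and estimates the
causal effect of cis-gene expression on a trans-gene by two-stage least
squares (equal to the Wald ratio for one instrument).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GWAS_SIGNIFICANCE = 5e-8
LOCUS_RADIUS = 1_000_000
#: coloc-convention effect-size prior sd: quantitative / binary (log-odds).
DEFAULT_W_QUANT = 0.15
DEFAULT_W_BINARY = 0.2


def define_gwas_loci(gwas: pd.DataFrame) -> pd.DataFrame:
    """Greedy lead-variant selection for approximately independent loci.

    Variants with p below genome-wide significance are taken in ascending
    p order; one is accepted iff no previously accepted variant lies
    within 1 Mb on the same chromosome.
    """
    sig = gwas[gwas["p"] < GWAS_SIGNIFICANCE].sort_values(
        "p", kind="stable"
    )
    accepted: list[pd.Series] = []
    for _, row in sig.iterrows():
        clash = any(
            row["chrom"] == acc["chrom"]
            and abs(int(row["pos"]) - int(acc["pos"])) <= LOCUS_RADIUS
            for acc in accepted
        )
        if not clash:
            accepted.append(row)
    return pd.DataFrame(accepted).reset_index(drop=True)


def wakefield_abf(
    beta: np.ndarray, se: np.ndarray, prior_sd: float = DEFAULT_W_QUANT
) -> np.ndarray:
    """Wakefield approximate Bayes factor (alternative vs null).

    With shrinkage r = W^2 / (W^2 + se^2) and z = beta / se:
    log ABF = 0.5 * (log(1 - r) + r * z^2).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    r = prior_sd**2 / (prior_sd**2 + se**2)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def beta_se_from_p(
    p: np.ndarray, maf: np.ndarray, n: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct (|beta|, se) from p, MAF and sample size.

    Uses the z-score and the variance approximation
    var(beta) ~ 1 / (2 n maf (1 - maf)); an approximation for summary
    stats lacking effect estimates.
    """
    z = stats.norm.isf(np.asarray(p, dtype=float) / 2.0)
    se = 1.0 / np.sqrt(2.0 * np.asarray(n) * np.asarray(maf) * (1 - np.asarray(maf)))
    return z * se, se


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    call: bool
    n_variants: int
    degenerate: bool = False

    @property
    def pp4_ratio(self) -> float:
        denom = self.pp[3] + self.pp[4]
        return float(self.pp[4] / denom) if denom > 0 else 0.0


def coloc_posteriors(
    log_abf1: np.ndarray,
    log_abf2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Five-hypothesis colocalization posteriors from per-variant log ABFs.

    H0 no association; H1/H2 one trait only; H3 both traits, distinct
    causal variants; H4 both traits, one shared variant.  Sums over
    variant configurations use the log-sum-exp of per-variant ABF
    products with priors p1, p2, p12; the call applies
    PP4 / (PP3 + PP4) > 0.9.
    """
    l1 = np.asarray(log_abf1, dtype=float)
    l2 = np.asarray(log_abf2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("traits must share one variant list")
    m = l1.size
    if m < 2:
        degenerate = True
    else:
        degenerate = False
    from scipy.special import logsumexp

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12_shared = logsumexp(l1 + l2)
    # H3: distinct causal variants = sum_{i != j} ABF1_i ABF2_j
    both = s1 + s2
    if np.isneginf(s12_shared):
        s3 = both
    else:
        # log(exp(both) - exp(shared)) computed stably
        diff = both + np.log1p(-np.exp(np.minimum(s12_shared - both, -1e-12)))
        s3 = diff
    log_terms = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            (np.log(p1) + np.log(p2) + s3) if m > 1 else -np.inf,
            (np.log(p12) + s12_shared) if p12 > 0 else -np.inf,
        ]
    )
    log_terms -= logsumexp(log_terms)
    pp = np.exp(log_terms)
    pp /= pp.sum()
    res = ColocResult(pp=pp, call=False, n_variants=m, degenerate=degenerate)
    res.call = res.pp4_ratio > 0.9 and pp[4] > 0
    return res


def coloc_from_summary(
    locus: pd.DataFrame,
    w1: float = DEFAULT_W_QUANT,
    w2: float = DEFAULT_W_QUANT,
    **priors,
) -> ColocResult:
    """Colocalization from a two-trait locus summary table.

    ``locus`` columns: beta_1, se_1, beta_2, se_2 (one row per shared
    variant).
    """
    if len(locus) < 2:
        raise ValueError("locus needs at least 2 variants")
    l1 = wakefield_abf(locus["beta_1"], locus["se_1"], w1)
    l2 = wakefield_abf(locus["beta_2"], locus["se_2"], w2)
    return coloc_posteriors(l1, l2, **priors)


@dataclass
class MrResult:
    estimate: float
    se: float
    t: float
    p: float
    first_stage_f: float
    n: int


def mendelian_randomization(
    instrument: np.ndarray,
    exposure: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    min_first_stage_t: float = 1.0,
) -> MrResult:
    """Two-stage least squares with a single genetic instrument.

    Stage 1 regresses the exposure (cis-gene expression) on the
    instrument (+covariates); stage 2 regresses the outcome (trans-gene
    expression) on the fitted exposure (+covariates).  For one instrument
    this equals the Wald ratio beta_yg / beta_xg.  Standard errors use
    the 2SLS residual (outcome minus estimate * observed exposure).
    """
    g = np.asarray(instrument, dtype=float)
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = g.size
    if covariates is None:
        c = np.ones((n, 1))
    else:
        c = np.hstack([np.ones((n, 1)), np.asarray(covariates, dtype=float)])
    q, _ = np.linalg.qr(c)

    def resid(v):
        return v - q @ (q.T @ v)

    g_r, x_r, y_r = resid(g), resid(x), resid(y)
    gg = float(g_r @ g_r)
    if gg <= 0:
        raise ValueError("constant instrument")
    beta_xg = float(g_r @ x_r) / gg
    df1 = n - c.shape[1] - 1
    rss1 = float(x_r @ x_r) - beta_xg**2 * gg
    se_xg = np.sqrt(max(rss1, 0.0) / df1 / gg)
    t_first = beta_xg / se_xg if se_xg > 0 else 0.0
    if abs(t_first) < min_first_stage_t:
        raise ValueError(
            f"weak instrument: first-stage |t| = {abs(t_first):.2f}"
        )
    beta_yg = float(g_r @ y_r) / gg
    estimate = beta_yg / beta_xg
    # 2SLS variance with residuals y - estimate * x
    u = y_r - estimate * x_r
    df = n - c.shape[1] - 1
    sigma2 = float(u @ u) / df
    xhat = beta_xg * g_r
    denom = float(xhat @ xhat)
    se = np.sqrt(sigma2 / denom)
    t = estimate / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), df)
    return MrResult(
        estimate=float(estimate), se=float(se), t=float(t), p=float(p),
        first_stage_f=float(t_first**2), n=n,
    )
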