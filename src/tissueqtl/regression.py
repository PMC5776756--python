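"""Linear-model engine for the association scans.

All scans are ordinary least squares of inverse-normal expression on
alternate-allele dosage with covariates.  For speed, covariates are
projected out of both phenotype and genotypes once (Frisch-Waugh-Lovell),
after which slope, standard error and the two-tailed t-test are exact
single-regressor formulas with ``n - n_covariates - 1`` residual degrees
of freedom.  The permutation machinery reuses the same projections so a
batch of permuted phenotypes reduces to one matrix product per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats


@dataclass
class ScanResult:
    """Vectorized OLS output for one phenotype against many regressors."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int


def covariate_basis(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis of the covariate column space (incl. intercept)."""
    if covariates is None or covariates.size == 0:
        c = np.ones((n, 1))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.shape[0] != n:
            raise ValueError("covariate rows must match sample count")
        has_const = any(
            np.allclose(c[:, j], c[0, j]) and c[0, j] != 0
            for j in range(c.shape[1])
        )
        if not has_const:
            c = np.hstack([np.ones((n, 1)), c])
    q, r = np.linalg.qr(c)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def residualize(m: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Project the covariate space out of columns-as-samples data."""
    return m - q @ (q.T @ m)


def ols_scan(
    y: np.ndarray,
    genotypes: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    q_basis: np.ndarray | None = None,
    g_resid: np.ndarray | None = None,
) -> ScanResult:
    """OLS of one phenotype on each genotype column, with covariates.

    Equivalent (exactly, by Frisch-Waugh-Lovell) to fitting
    ``y ~ 1 + covariates + g`` per variant and reading off the genotype
    slope, its standard error and the two-tailed t-test p-value.
    Rank-deficient variants (zero residual variance) get ``se = inf`` and
    ``p = 1``.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if q_basis is None:
        q_basis = covariate_basis(covariates, n)
    df = n - q_basis.shape[1] - 1
    if df < 1:
        raise ValueError("not enough samples for the model")
    if g_resid is None:
        g_resid = residualize(np.asarray(genotypes, dtype=float), q_basis)
    y_res = y - q_basis @ (q_basis.T @ y)

    gtg = np.einsum("ij,ij->j", g_resid, g_resid)
    gty = g_resid.T @ y_res
    yty = float(y_res @ y_res)
    ok = gtg > 1e-12
    beta = np.zeros(g_resid.shape[1])
    se = np.full(g_resid.shape[1], np.inf)
    beta[ok] = gty[ok] / gtg[ok]
    rss = np.maximum(yty - beta**2 * gtg, 0.0)
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2[ok] / gtg[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok & (se > 0), beta / se, 0.0)
        # perfect fit: zero residual variance with a nonzero slope
        exact = ok & (se == 0) & (beta != 0)
        t[exact] = np.sign(beta[exact]) * np.inf
    p = np.where(ok, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return ScanResult(beta=beta, se=se, t=t, p=p, df=df)


def permutation_min_p(
    y: np.ndarray,
    g_resid: np.ndarray,
    q_basis: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Minimum nominal p over variants for ``n_perm`` phenotype permutations.

    The phenotype is permuted across samples while covariates stay fixed
    to their samples; each permuted phenotype is then residualized against
    the covariates exactly as the observed one.
    """
    n = y.shape[0]
    df = n - q_basis.shape[1] - 1
    gtg = np.einsum("ij,ij->j", g_resid, g_resid)
    ok = gtg > 1e-12
    g_ok = g_resid[:, ok]
    norms = np.sqrt(gtg[ok])
    if g_ok.shape[1] == 0:
        return np.ones(n_perm)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = y[perms]  # (B, n)
    yp_res = yp - (yp @ q_basis) @ q_basis.T
    yp_norm = np.linalg.norm(yp_res, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yp_res @ g_ok) / (yp_norm[:, None] * norms[None, :])
    r = np.clip(r, -1.0, 1.0)
    r2max = np.max(r**2, axis=1)
    with np.errstate(divide="ignore"):
        tmax2 = df * r2max / (1.0 - r2max)
    p_min = 2.0 * stats.t.sf(np.sqrt(tmax2), df)
    return np.clip(p_min, 0.0, 1.0)


def beta_mle(x: np.ndarray, tol: float = 1e-8, max_iter: int = 100) -> tuple[float, float]:
    """Maximum-likelihood Beta(a, b) fit by Newton iteration.

    Starts from method-of-moments and solves the digamma score equations
    with a full 2x2 Newton step (trigamma Hessian).  Used to extrapolate
    gene-level empirical p-values from permutation minimum p-values.
    """
    x = np.asarray(x, dtype=float)
    x = np.clip(x, 1e-300, 1.0 - 1e-12)
    m = x.mean()
    v = x.var()
    if v <= 0:
        return 1.0, 1.0
    common = m * (1.0 - m) / v - 1.0
    a = max(m * common, 1e-3)
    b = max((1.0 - m) * common, 1e-3)
    mlog = np.log(x).mean()
    mlog1 = np.log1p(-x).mean()
    for _ in range(max_iter):
        psi_ab = special.psi(a + b)
        ga = psi_ab - special.psi(a) + mlog
        gb = psi_ab - special.psi(b) + mlog1
        tri_ab = special.polygamma(1, a + b)
        haa = tri_ab - special.polygamma(1, a)
        hbb = tri_ab - special.polygamma(1, b)
        hab = tri_ab
        det = haa * hbb - hab * hab
        if abs(det) < 1e-300:
            break
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        step = 1.0
        while (a - step * da <= 0) or (b - step * db <= 0):
            step *= 0.5
            if step < 1e-8:
                break
        a_new = a - step * da
        b_new = b - step * db
        if abs(a_new - a) < tol * (1 + abs(a)) and abs(b_new - b) < tol * (
            1 + abs(b)
        ):
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    return float(a), float(b)
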