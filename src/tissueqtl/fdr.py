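"""False-discovery-rate machinery shared across stages.

Storey's pi0/pi1 estimator and q-values serve the cis eGene calls and the
cross-tissue replication analysis; Benjamini-Hochberg step-up serves the
trans scans and ASE imbalance calls.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def storey_pi0(
    p: np.ndarray, lambda_grid: np.ndarray | None = None
) -> float:
    """Estimate pi0, the proportion of true nulls, from a p-value set.

    ``pi0(lambda) = #{p > lambda} / (n * (1 - lambda))`` is evaluated on a
    grid and smoothed with a cubic polynomial in lambda; the smoothed
    value at the largest lambda is returned, clipped to [0, 1].  With a
    single grid point the raw estimate is used.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size < 50:
        logger.warning("pi0 estimated from %d p-values; unstable", p.size)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
    grid = grid[grid < p.max()] if (grid < p.max()).any() else grid[:1]
    pi0_lambda = np.array(
        [(p > lam).mean() / (1.0 - lam) for lam in grid]
    )
    if len(grid) >= 4:
        # cubic smoother evaluated at the largest lambda; grid points are
        # weighted by their binomial precision (var ~ 1/(1 - lambda)), which
        # tames the noisy right edge at small p-value counts
        w = np.sqrt(1.0 - grid)
        coeffs = np.polyfit(grid, pi0_lambda, deg=3, w=w)
        pi0 = float(np.polyval(coeffs, grid.max()))
    else:
        pi0 = float(pi0_lambda[-1])
    return float(np.clip(pi0, max(1.0 / p.size, 1e-8), 1.0))


def storey_qvalues(
    p: np.ndarray, lambda_grid: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values and the pi0 estimate they used.

    q_i = min over p_(j) >= p_(i) of pi0 * n * p_(j) / j  (monotone
    step-up on the ordered p-values).
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 1:
        return np.clip(p, 0, 1), 1.0
    pi0 = storey_pi0(p, lambda_grid) if n >= 10 else 1.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * n * ranked / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(n)
    out[order] = q
    return out, pi0


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out
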