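"""Storey positive-false-discovery-rate q-values.

pi0 (the fraction of true nulls) is estimated from the right tail of the
p-value distribution, pi0(lambda) = #{p > lambda} / (m (1 - lambda)),
over a lambda grid with a cubic-polynomial smoother evaluated at the
largest lambda; for small collections (m < 100) the tail estimate is too
noisy to smooth and a single fixed lambda = 0.5 is used.  q-values are the
usual step-up transform q_i = min_{p_j >= p_i} pi0 * m * p_j / rank_j,
monotone nondecreasing in p.
"""

from __future__ import annotations

import numpy as np

LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(pvalues: np.ndarray, lambda_grid: np.ndarray | None = None) -> float:
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambda_grid is None and m < 100:
        lam = 0.5
        return float(min(1.0, np.mean(p > lam) / (1.0 - lam)))
    grid = LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size == 1:
        lam = float(grid[0])
        return float(min(1.0, np.mean(p > lam) / (1.0 - lam)))
    pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
    coef = np.polynomial.polynomial.polyfit(grid, pi0_lam, deg=3)
    pi0 = float(np.polynomial.polynomial.polyval(grid.max(), coef))
    return float(min(1.0, max(pi0, 1.0 / m)))


def qvalues(pvalues: np.ndarray,
            lambda_grid: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Per-test q-values and the pi0 estimate for a p-value collection."""
    p = np.asarray(pvalues, float)
    pi0 = estimate_pi0(p, lambda_grid)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0
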