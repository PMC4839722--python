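"""Small shared statistical primitives."""

from __future__ import annotations

import numpy as np


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    For sorted p-values p_(1) <= ... <= p_(m),
    ``q_i = min_{j >= rank(i)} m * p_(j) / j`` capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # running minimum from the largest rank down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def density_mode(values, grid_lo: float = -1.0, grid_hi: float = 1.0,
                 n_grid: int = 2001) -> float:
    """Location of the highest peak of a Gaussian kernel density estimate.

    Silverman's rule is used for the bandwidth (scipy's default for
    ``gaussian_kde`` is Scott's; Silverman is requested explicitly so the
    bandwidth is recorded and reproducible).
    """
    from scipy.stats import gaussian_kde

    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 finite values for a density mode")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(grid_lo, grid_hi, n_grid)
    return float(grid[np.argmax(kde(grid))])
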