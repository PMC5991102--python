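"""Posterior summaries: marginal modes and equal-tailed credible bounds."""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde

__all__ = ["marginal_mode", "credible_interval", "summarize_draws"]


def marginal_mode(draws: np.ndarray, n_grid: int = 512) -> float:
    """Maximizer of a Gaussian KDE of a 1-D marginal.

    Degenerate (zero-variance) marginals return their common value.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if np.ptp(draws) == 0:
        return float(draws[0])
    kde = gaussian_kde(draws)
    grid = np.linspace(draws.min(), draws.max(), n_grid)
    return float(grid[np.argmax(kde(grid))])


def credible_interval(draws: np.ndarray, level: float = 0.95):
    """Equal-tailed credible bounds at the given level."""
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(np.asarray(draws, dtype=float).ravel(), [tail, 100 - tail])
    return float(lo), float(hi)


def summarize_draws(draws: np.ndarray, names, level: float = 0.95):
    """Per-parameter (mode, lower, upper) table for (n_draws, ndim) draws."""
    import pandas as pd

    rows = []
    for j, name in enumerate(names):
        mode = marginal_mode(draws[:, j])
        lo, hi = credible_interval(draws[:, j], level)
        rows.append({"parameter": name, "mode": mode, "lower": lo, "upper": hi})
    return pd.DataFrame(rows).set_index("parameter")
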