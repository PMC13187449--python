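"""Independent oracles used by the test suite.

These are deliberately naive (grid search, exhaustive enumeration) and share
no code with the implementations they check.
"""

from __future__ import annotations

import numpy as np


def grid_minimize_alpha(g: np.ndarray, r: np.ndarray, lo=-100.0, hi=100.0) -> float:
    """Brute-force 1-D minimizer of sum((g - alpha*r)**2) by refined grid search."""
    g = np.asarray(g, dtype=float)
    r = np.asarray(r, dtype=float)
    alpha_lo, alpha_hi = lo, hi
    best = None
    for _ in range(6):  # successive refinement down to ~1e-8 spacing
        grid = np.linspace(alpha_lo, alpha_hi, 2001)
        sse = ((g[None, :] - grid[:, None] * r[None, :]) ** 2).sum(axis=1)
        k = int(np.argmin(sse))
        best = grid[k]
        step = grid[1] - grid[0]
        alpha_lo, alpha_hi = best - 2 * step, best + 2 * step
    return float(best)


def enumerate_dtw(a: np.ndarray, b: np.ndarray) -> float:
    """Exact DTW cost by exhaustive enumeration of all monotone warping paths.

    Sequences are 1-D or (time, dims); local cost is the Euclidean distance.
    Exponential in sequence length — use only for lengths <= ~6.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float).T).T if np.asarray(a).ndim == 1 else np.asarray(a, float)
    b = np.atleast_2d(np.asarray(b, dtype=float).T).T if np.asarray(b).ndim == 1 else np.asarray(b, float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n, m = len(a), len(b)
    cost = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))

    best = [np.inf]

    def walk(i: int, j: int, acc: float) -> None:
        acc += cost[i, j]
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return float(best[0])
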