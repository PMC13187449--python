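"""Dynamic time warping primitives.

Dependent multivariate DTW: one warping path is shared across all
dimensions and the local cost between two multivariate samples is their
Euclidean distance.  Classic O(n·m) dynamic program with unit step weights
over steps (1,0), (0,1), (1,1); ``dtw_distance`` of two identical
sequences is 0, and the measure is symmetric and nonnegative (it is not a
metric — the triangle inequality can fail, as for any unconstrained DTW).

Also here: DTW barycenter averaging (DBA) used for cluster representatives.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

__all__ = ["dtw_distance", "dtw_path", "dba_barycenter"]


def _as_2d(seq: np.ndarray) -> np.ndarray:
    a = np.asarray(seq, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise InputError("sequence must be 1-D or (time, dims) 2-D")
    return a


def _cost_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _accumulate(c: np.ndarray) -> np.ndarray:
    n, m = c.shape
    acc = np.full((n, m), np.inf)
    acc[0, 0] = c[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + c[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + c[i, 0]
        row_prev = acc[i - 1]
        row = acc[i]
        for j in range(1, m):
            row[j] = c[i, j] + min(row_prev[j], row[j - 1], row_prev[j - 1])
    return acc


def dtw_distance(seq_a: np.ndarray, seq_b: np.ndarray) -> float:
    """Dependent multivariate DTW cost between two (time, dims) sequences."""
    a, b = _as_2d(seq_a), _as_2d(seq_b)
    if a.shape[1] != b.shape[1]:
        raise InputError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    return float(_accumulate(_cost_matrix(a, b))[-1, -1])


def dtw_path(seq_a: np.ndarray, seq_b: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Optimal warping path and its cost."""
    a, b = _as_2d(seq_a), _as_2d(seq_b)
    if a.shape[1] != b.shape[1]:
        raise InputError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    acc = _accumulate(_cost_matrix(a, b))
    i, j = acc.shape[0] - 1, acc.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            k = int(np.argmin([acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]]))
            if k == 0:
                i, j = i - 1, j - 1
            elif k == 1:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return path, float(acc[-1, -1])


def dba_barycenter(
    sequences: list[np.ndarray], init: np.ndarray, n_iter: int = 10
) -> np.ndarray:
    """DTW barycenter averaging.

    Starting from ``init`` (same (time, dims) shape as the members), each
    iteration aligns every member to the current barycenter along its
    optimal warping path and replaces each barycenter sample by the mean of
    the member samples mapped onto it.  The iterate with the lowest summed
    DTW cost to the members is returned, so the result is never worse than
    the initialisation.
    """
    seqs = [_as_2d(s) for s in sequences]
    bary = _as_2d(init).copy()
    best = bary.copy()
    best_cost = sum(dtw_distance(bary, s) for s in seqs)
    for _ in range(n_iter):
        sums = np.zeros_like(bary)
        counts = np.zeros(len(bary))
        for s in seqs:
            path, _ = dtw_path(bary, s)
            for i, j in path:
                sums[i] += s[j]
                counts[i] += 1
        nonzero = counts > 0
        bary[nonzero] = sums[nonzero] / counts[nonzero, None]
        cost = sum(dtw_distance(bary, s) for s in seqs)
        if cost < best_cost - 1e-12:
            best, best_cost = bary.copy(), cost
        else:
            break
    return best
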