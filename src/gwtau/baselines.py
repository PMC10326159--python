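"""Baseline trajectory distances: flat Euclidean and unconstrained DTW.

Both baselines compare 1D series on their raw value sequences (for series
that were embedded as ``(t, y)`` curves, the stored raw values are used);
multivariate series are compared coordinate-wise.  This differs from GW_tau,
which always works on the embedded curve — a deliberate asymmetry following
the usual conventions for these distances.

DTW dialect: unconstrained warping (no window), symmetric steps
(1,0), (0,1), (1,1), Euclidean local cost, total cost = sum of local costs
along the path — the common textbook/Matlab default.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .exceptions import InvalidInputError
from .trajectory import Trajectory, as_trajectory

__all__ = ["euclidean_distance", "dtw_distance", "dtw_brute_force"]


def _baseline_points(t: Trajectory | np.ndarray) -> np.ndarray:
    return as_trajectory(t).baseline_matrix()


def euclidean_distance(a, b) -> float:
    """Flat Euclidean distance (exponent 2) between equal-shape series.

    The square root of the sum over all time indices and coordinates of
    squared differences.
    """
    pa, pb = _baseline_points(a), _baseline_points(b)
    if pa.shape != pb.shape:
        raise InvalidInputError(
            f"Euclidean distance needs equal shapes, got {pa.shape} vs {pb.shape}"
        )
    return float(np.sqrt(np.sum((pa - pb) ** 2)))


@njit(cache=False)
def _dtw_kernel(a: np.ndarray, b: np.ndarray):
    """Rolling-row DP for unconstrained DTW; returns (cost, cell count)."""
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(m + 1):
        prev[j] = np.inf
    prev[0] = 0.0
    ops = 0
    for i in range(1, n + 1):
        cur[0] = np.inf
        for j in range(1, m + 1):
            c = 0.0
            for k in range(a.shape[1]):
                diff = a[i - 1, k] - b[j - 1, k]
                c += diff * diff
            c = np.sqrt(c)
            best = prev[j]  # insertion
            if prev[j - 1] < best:  # match
                best = prev[j - 1]
            if cur[j - 1] < best:  # deletion
                best = cur[j - 1]
            cur[j] = c + best
            ops += 1
        prev, cur = cur, prev
    return prev[m], ops


def dtw_distance(a, b, return_ops: bool = False):
    """Unconstrained dynamic time warping distance.

    Minimal sum of pointwise Euclidean costs over monotone warping paths
    from (1, 1) to (n, m); O(n*m) dynamic program.  With
    ``return_ops=True`` also returns the number of DP cell updates.

    Note: DTW is symmetric with zero self-distance but is *not* a metric
    (the triangle inequality can fail).
    """
    pa, pb = _baseline_points(a), _baseline_points(b)
    if pa.shape[1] != pb.shape[1]:
        raise InvalidInputError(
            f"DTW needs equal dimensions, got {pa.shape[1]} vs {pb.shape[1]}"
        )
    cost, ops = _dtw_kernel(
        np.ascontiguousarray(pa, dtype=np.float64),
        np.ascontiguousarray(pb, dtype=np.float64),
    )
    if return_ops:
        return float(cost), int(ops)
    return float(cost)


def dtw_brute_force(a, b) -> float:
    """DTW by exhaustive enumeration of all monotone warping paths.

    Exponential reference implementation for validating the dynamic
    program on tiny inputs (n, m <= ~7).
    """
    pa, pb = _baseline_points(a), _baseline_points(b)
    if pa.shape[1] != pb.shape[1]:
        raise InvalidInputError("dimension mismatch")
    n, m = pa.shape[0], pb.shape[0]

    def cell(i, j):
        return float(np.linalg.norm(pa[i] - pb[j]))

    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc + cell(i + 1, j + 1))
        if i + 1 < n:
            walk(i + 1, j, acc + cell(i + 1, j))
        if j + 1 < m:
            walk(i, j + 1, acc + cell(i, j + 1))

    walk(0, 0, cell(0, 0))
    return best[0]
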