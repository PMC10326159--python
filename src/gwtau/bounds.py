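"""Reference computations for validating GW_tau.

* :func:`wasserstein_1d_lp_oracle` — the 1D Wasserstein distance computed
  as an explicit transport linear program (no closed form), used as an
  independent oracle against the closed-form fast path.
* :func:`local_distance_distribution` — the distribution of intrinsic
  (arc-length) distances seen from any anchor point of a trajectory; the
  anchor-at-start case is exactly the GW_tau distance profile.
* :func:`tlb` — Memoli's Third Lower Bound on the Gromov-Wasserstein
  distance, built from 1D Wasserstein comparisons of local distance
  distributions and one outer transport LP.  For any pair of trajectories
  ``TLB <= GW <= GW_tau``, which brackets the (intractable) GW value.

This module is a validator, not a fast path: local distance distributions
are generally not monotone, so closed forms here sort their supports first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .exceptions import ComputationError, InvalidInputError, InvalidParameterError
from .metric import _check_p, _w1d_sorted_uniform, cumulative_arclength
from .trajectory import Trajectory, as_trajectory

__all__ = [
    "LocalDistanceDistribution",
    "local_distance_distribution",
    "wasserstein_1d_lp_oracle",
    "tlb",
]


@dataclass
class LocalDistanceDistribution:
    """Distances from one anchor point to every point of a trajectory."""

    anchor_index: int
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v[self.anchor_index] != 0.0 or np.any(v < 0):
            raise InvalidInputError("invalid local distance distribution")
        self.values = v
        self.weights = np.asarray(self.weights, dtype=float)


def local_distance_distribution(
    traj: Trajectory | np.ndarray, anchor: int
) -> LocalDistanceDistribution:
    """Arc-length distances from the anchor point to every point.

    ``values[k] = |cumlen[k] - cumlen[anchor]|``; with ``anchor=0`` this
    reproduces the distance-from-start profile.
    """
    traj = as_trajectory(traj)
    n = traj.n_points
    if not (0 <= anchor < n):
        raise InvalidInputError(f"anchor {anchor} out of range [0, {n})")
    cum = cumulative_arclength(traj).values
    return LocalDistanceDistribution(
        anchor_index=anchor,
        values=np.abs(cum - cum[anchor]),
        weights=np.full(n, 1.0 / n),
    )


def _transport_lp(cost: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Solve ``min <cost, P>`` over couplings P with marginals a, b.

    Returns (optimal value, optimal plan).  Exact (simplex/IPM via HiGHS);
    intended for small instances, n*m up to ~10^4 variables.
    """
    n, m = cost.shape
    # row-sum and column-sum equality constraints; drop the last column
    # constraint (redundant given total mass 1) for full row rank
    rows = []
    cols = []
    for i in range(n):
        rows.extend([i] * m)
        cols.extend(range(i * m, (i + 1) * m))
    for j in range(m - 1):
        rows.extend([n + j] * n)
        cols.extend(range(j, n * m, m))
    A = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n + m - 1, n * m)
    )
    b_eq = np.concatenate((a, b[:-1]))
    res = linprog(cost.ravel(), A_eq=A.tocsr(), b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if res.status != 0:
        raise ComputationError(
            f"transport LP failed (status {res.status}): {res.message}"
        )
    return float(res.fun), res.x.reshape(n, m)


def wasserstein_1d_lp_oracle(z_values, z_weights, w_values, w_weights,
                             p: float = 2.0) -> float:
    """1D p-Wasserstein distance via an exact transport linear program.

    Independent of the closed-form path: builds the full ``|z_i - w_j|^p``
    cost matrix and solves the LP over all couplings.
    """
    p = _check_p(p)
    zv = np.asarray(z_values, dtype=float)
    wv = np.asarray(w_values, dtype=float)
    zw = np.asarray(z_weights, dtype=float)
    ww = np.asarray(w_weights, dtype=float)
    if abs(zw.sum() - 1.0) > 1e-9 or abs(ww.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("weights must sum to 1 (within 1e-9)")
    cost = np.abs(zv[:, None] - wv[None, :]) ** p
    val, _ = _transport_lp(cost, zw, ww)
    return max(val, 0.0) ** (1.0 / p)


def tlb(a, b, p: float = 2.0) -> float:
    """Third Lower Bound (TLB) on the Gromov-Wasserstein distance.

    Cost ``C[i, j]`` is the 1D p-Wasserstein distance between the local
    distance distributions anchored at point i of ``a`` and point j of
    ``b`` (closed form on sorted supports); the bound is
    ``(1/2) * (min_coupling sum C[i,j]^p mu_ij)^{1/p}`` with uniform
    marginals, solved exactly as a transport LP.
    """
    p = _check_p(p)
    a = as_trajectory(a, "a")
    b = as_trajectory(b, "b")
    ca = cumulative_arclength(a).values
    cb = cumulative_arclength(b).values
    n, m = ca.size, cb.size
    # local distance distributions: |cum - cum[anchor]|, sorted per anchor
    la = np.sort(np.abs(ca[None, :] - ca[:, None]), axis=1)
    lb = np.sort(np.abs(cb[None, :] - cb[:, None]), axis=1)
    C = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            C[i, j] = _w1d_sorted_uniform(la[i], lb[j], p)  # already ^p
    val, _ = _transport_lp(C, np.full(n, 1.0 / n), np.full(m, 1.0 / m))
    return 0.5 * max(val, 0.0) ** (1.0 / p)
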