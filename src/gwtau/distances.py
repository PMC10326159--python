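"""Estimator classes for the three trajectory distances.

These are thin sklearn-style wrappers (``fit`` / ``transform`` /
``pairwise``) over the module-level distance functions; ``GWTau`` caches
arc-length profiles of the fitted trajectories so repeated transforms do
not recompute them.
"""

from __future__ import annotations

import numpy as np

from . import baselines
from .base import PairwiseTrajectoryDistance, _coerce_list
from .exceptions import InvalidInputError
from .metric import _check_p, _w1d_sorted_uniform, cumulative_arclength

__all__ = ["GWTau", "DynamicTimeWarping", "FlatEuclidean"]


class GWTau(PairwiseTrajectoryDistance):
    """GW_tau distance transformer.

    Parameters
    ----------
    p : float, default 2.0
        Wasserstein exponent, any value in [1, inf).
    """

    metric_name = "gw_tau"

    def __init__(self, p: float = 2.0):
        self.p = p

    def _dist(self, a, b) -> float:
        p = _check_p(self.p)
        za = cumulative_arclength(a).values
        zb = cumulative_arclength(b).values
        return _w1d_sorted_uniform(za, zb, p) ** (1.0 / p)

    def fit(self, X, y=None):
        super().fit(X, y)
        self.profiles_ = [cumulative_arclength(t).values for t in self.train_]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "profiles_"):
            raise InvalidInputError("transformer is not fitted")
        p = _check_p(self.p)
        test = [cumulative_arclength(t).values for t in _coerce_list(X)]
        out = np.empty((len(test), len(self.profiles_)))
        for i, za in enumerate(test):
            for j, zb in enumerate(self.profiles_):
                out[i, j] = _w1d_sorted_uniform(za, zb, p) ** (1.0 / p)
        return out


class DynamicTimeWarping(PairwiseTrajectoryDistance):
    """Unconstrained DTW distance transformer (see :mod:`gwtau.baselines`)."""

    metric_name = "dtw"

    def _dist(self, a, b) -> float:
        return baselines.dtw_distance(a, b)


class FlatEuclidean(PairwiseTrajectoryDistance):
    """Flat Euclidean distance transformer; requires equal-shape series."""

    metric_name = "euclidean"

    def _dist(self, a, b) -> float:
        return baselines.euclidean_distance(a, b)


#: registry used by the CLI and task helpers
DISTANCES = {
    "gwtau": GWTau,
    "gw_tau": GWTau,
    "dtw": DynamicTimeWarping,
    "euclid": FlatEuclidean,
    "euclidean": FlatEuclidean,
}


def make_distance(name: str, p: float = 2.0) -> PairwiseTrajectoryDistance:
    """Instantiate a distance transformer by name."""
    try:
        cls = DISTANCES[name.lower()]
    except KeyError:
        raise InvalidInputError(
            f"unknown metric {name!r}; choose from gwtau, dtw, euclid"
        ) from None
    return cls(p=p) if cls is GWTau else cls()
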