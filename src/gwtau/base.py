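"""scikit-learn style pairwise-distance transformers.

Each distance is an estimator: ``fit`` stores the reference (training)
trajectories, ``transform`` returns the cross-distance matrix between new
trajectories and the stored ones — the "precomputed metric" convention, so
the transformers compose with sklearn classifiers and clusterers that accept
``metric='precomputed'``.  ``pairwise`` returns the full symmetric matrix of
one collection with provenance metadata.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InvalidInputError
from .metric import DistanceMatrix
from .trajectory import LabeledDataset, Trajectory, as_trajectory


def _coerce_list(X) -> list[Trajectory]:
    if isinstance(X, LabeledDataset):
        return list(X)
    if isinstance(X, Trajectory):
        return [X]
    return [as_trajectory(x, id=f"traj_{i}") for i, x in enumerate(X)]


class PairwiseTrajectoryDistance(TransformerMixin, BaseEstimator):
    """Base class for trajectory distances exposed as transformers."""

    #: short metric name recorded in DistanceMatrix metadata
    metric_name: str = "abstract"

    def _dist(self, a: Trajectory, b: Trajectory) -> float:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y=None):
        """Store the reference trajectories."""
        self.train_ = _coerce_list(X)
        if not self.train_:
            raise InvalidInputError("empty training set")
        self.n_features_in_ = len(self.train_)
        return self

    def transform(self, X) -> np.ndarray:
        """Cross-distance matrix of shape (len(X), n_train)."""
        if not hasattr(self, "train_"):
            raise InvalidInputError("transformer is not fitted")
        test = _coerce_list(X)
        out = np.empty((len(test), len(self.train_)))
        for i, a in enumerate(test):
            for j, b in enumerate(self.train_):
                out[i, j] = self._dist(a, b)
        return out

    def pairwise(self, X) -> DistanceMatrix:
        """Symmetric distance matrix of one collection."""
        trajs = _coerce_list(X)
        ids = [t.id for t in trajs]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate trajectory ids")
        K = len(trajs)
        D = np.zeros((K, K))
        for i in range(K):
            for j in range(i + 1, K):
                D[i, j] = D[j, i] = self._dist(trajs[i], trajs[j])
        return DistanceMatrix(
            ids=ids, D=D, metric=self.metric_name, p=getattr(self, "p", 2.0)
        )
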