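"""Distance-based analysis workflow: 1-NN classification, clustering on a
precomputed distance matrix, classical MDS embedding with k-means, partition
scoring, and assessment of trajectory-averaging procedures.

Everything here consumes distance matrices (or embeddings derived from
them), never the raw trajectories — so any distance transformer from
:mod:`gwtau.distances` plugs in, and results under GW_tau are automatically
invariant to rigid motions of the input trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .exceptions import InvalidInputError, InvalidParameterError
from .metric import DistanceMatrix, gw_tau_matrix
from .trajectory import LabeledDataset, Trajectory

__all__ = [
    "EmbeddingResult",
    "OneNearestNeighbor",
    "knn1_classify",
    "HierarchicalClustering",
    "hierarchical_cluster",
    "KMedoids",
    "kmedoids_cluster",
    "ClassicalMDS",
    "mds_embed",
    "kmeans_on_embedding",
    "clustering_quality",
    "mean_trajectory",
    "averaging_assessment",
]


@dataclass
class EmbeddingResult:
    """Planar (or dim-dimensional) coordinates from an MDS embedding."""

    ids: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape[0] != len(self.ids) or not np.isfinite(c).all():
            raise InvalidInputError("embedding coords malformed")
        self.coords = c


def _as_array(D) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return D.D
    return np.asarray(D, dtype=float)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class OneNearestNeighbor(BaseEstimator):
    """1-NN classifier on precomputed cross-distances.

    ``fit`` stores the training labels; ``predict`` takes the
    (n_test, n_train) cross-distance matrix and returns, for each test
    item, the label of the minimum-distance training item.  Ties are
    broken by the lowest training index (deterministic).
    """

    def fit(self, X, y):
        y = np.asarray(y)
        if y.size == 0:
            raise InvalidInputError("empty training set")
        if X is not None:
            X = _as_array(X)
            if X.shape[-1] != y.size:
                raise InvalidInputError("labels do not match distance columns")
        self.train_labels_ = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X) -> np.ndarray:
        cross = _as_array(X)
        if cross.ndim != 2 or cross.shape[1] != self.train_labels_.size:
            raise InvalidInputError(
                f"cross-distance table must be (n_test, {self.train_labels_.size})"
            )
        # np.argmin returns the first (lowest-index) minimizer
        return self.train_labels_[np.argmin(cross, axis=1)]


def knn1_classify(cross_distances, train_labels) -> np.ndarray:
    """Label each test item by its nearest training item (lowest-index ties)."""
    clf = OneNearestNeighbor().fit(None, train_labels)
    return clf.predict(cross_distances)


# ---------------------------------------------------------------------------
# clustering on a precomputed distance matrix
# ---------------------------------------------------------------------------

class HierarchicalClustering(ClusterMixin, BaseEstimator):
    """Agglomerative clustering (single or complete linkage) on a
    precomputed distance matrix, cut at ``n_clusters`` groups."""

    def __init__(self, n_clusters: int = 2, linkage: str = "single"):
        self.n_clusters = n_clusters
        self.linkage = linkage

    def fit(self, X, y=None):
        D = _as_array(X)
        K = D.shape[0]
        if not (1 <= self.n_clusters <= K):
            raise InvalidParameterError(f"n_clusters must be in [1, {K}]")
        if self.linkage not in ("single", "complete"):
            raise InvalidParameterError("linkage must be 'single' or 'complete'")
        if K == 1:
            self.labels_ = np.zeros(1, dtype=int)
            return self
        Z = scipy_linkage(squareform(D, checks=False), method=self.linkage)
        self.labels_ = fcluster(Z, t=self.n_clusters, criterion="maxclust") - 1
        return self


def hierarchical_cluster(D, linkage: str = "single", k: int = 2) -> np.ndarray:
    return HierarchicalClustering(n_clusters=k, linkage=linkage).fit_predict(D)


class KMedoids(ClusterMixin, BaseEstimator):
    """PAM-style k-medoids on a precomputed distance matrix.

    Seeded random medoid initialization with ``n_init`` restarts; within
    each restart, alternate assignment and medoid update (each medoid is
    replaced by the member minimizing the within-cluster distance sum)
    until the medoid set stabilizes.  The lowest-cost restart wins;
    identical seeds give identical labels.
    """

    def __init__(self, n_clusters: int = 2, n_init: int = 50,
                 max_iter: int = 100, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        D = _as_array(X)
        K = D.shape[0]
        k = self.n_clusters
        if not (1 <= k <= K):
            raise InvalidParameterError(f"n_clusters must be in [1, {K}]")
        rng = np.random.default_rng(self.random_state)
        best_cost = np.inf
        best = None
        for _ in range(self.n_init):
            medoids = rng.choice(K, size=k, replace=False)
            for _ in range(self.max_iter):
                labels = np.argmin(D[:, medoids], axis=1)
                new = medoids.copy()
                for c in range(k):
                    members = np.flatnonzero(labels == c)
                    if members.size == 0:
                        # revive empty cluster at the worst-served point
                        far = np.argmax(D[np.arange(K), medoids[labels]])
                        new[c] = far
                        continue
                    within = D[np.ix_(members, members)].sum(axis=0)
                    new[c] = members[np.argmin(within)]
                if set(new) == set(medoids):
                    medoids = new
                    break
                medoids = new
            labels = np.argmin(D[:, medoids], axis=1)
            cost = D[np.arange(K), medoids[labels]].sum()
            if cost < best_cost - 1e-15:
                best_cost = cost
                best = (labels, medoids)
        self.labels_, self.medoid_indices_ = best
        self.inertia_ = best_cost
        return self


def kmedoids_cluster(D, k: int = 2, seed: int | None = 0,
                     n_init: int = 50) -> np.ndarray:
    return KMedoids(n_clusters=k, random_state=seed, n_init=n_init).fit_predict(D)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

class ClassicalMDS(TransformerMixin, BaseEstimator):
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix, takes the top
    ``n_components`` eigenpairs of ``B = -J D^2 J / 2``, and scales
    eigenvectors by the square roots of their (clipped) eigenvalues.
    Deterministic: signs are fixed so each coordinate axis has a positive
    largest-magnitude loading.  ``eigenvalues_`` keeps the full spectrum as
    a diagnostic of how Euclidean-realizable the distances are.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit_transform(self, X, y=None) -> np.ndarray:
        D = _as_array(X)
        K = D.shape[0]
        dim = self.n_components
        if dim > K - 1:
            raise InvalidParameterError(f"n_components must be <= {K - 1}")
        J = np.eye(K) - np.full((K, K), 1.0 / K)
        B = -0.5 * J @ (D ** 2) @ J
        vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        top = vecs[:, :dim] * np.sqrt(np.clip(vals[:dim], 0.0, None))
        # deterministic sign convention
        for c in range(top.shape[1]):
            col = top[:, c]
            if col.any() and col[np.argmax(np.abs(col))] < 0:
                top[:, c] = -col
        self.eigenvalues_ = vals
        self.embedding_ = top
        return top

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def transform(self, X) -> np.ndarray:
        # classical MDS has no out-of-sample map; transform re-embeds
        return self.fit_transform(X)


def mds_embed(D: DistanceMatrix, dim: int = 2) -> EmbeddingResult:
    """Embed a distance matrix into ``dim`` dimensions by classical MDS."""
    mds = ClassicalMDS(n_components=dim)
    coords = mds.fit_transform(D)
    ids = D.ids if isinstance(D, DistanceMatrix) else [
        str(i) for i in range(coords.shape[0])
    ]
    return EmbeddingResult(ids=list(ids), coords=coords,
                           eigenvalues=mds.eigenvalues_)


def kmeans_on_embedding(emb: EmbeddingResult | np.ndarray, k: int,
                        seed: int | None = 0, n_init: int = 50) -> np.ndarray:
    """Lloyd's k-means with seeded multi-restart on embedded coordinates."""
    coords = emb.coords if isinstance(emb, EmbeddingResult) else np.asarray(emb)
    if not (1 <= k <= coords.shape[0]):
        raise InvalidParameterError("invalid number of clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(coords)


# ---------------------------------------------------------------------------
# scoring and averaging
# ---------------------------------------------------------------------------

def clustering_quality(pred_labels, true_labels) -> dict:
    """Score a partition against ground truth.

    ``error_count`` is the minimum number of mismatched items over all
    one-to-one matchings of predicted to true labels (Hungarian matching on
    the contingency table); ``ari`` is the adjusted Rand index.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise InvalidInputError("label vectors must have equal length")
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(true, return_inverse=True)
    cont = np.zeros((pu.size, tu.size), dtype=int)
    np.add.at(cont, (pi, ti), 1)
    rows, cols = linear_sum_assignment(-cont)
    matched = cont[rows, cols].sum()
    return {
        "error_count": int(pred.size - matched),
        "ari": float(adjusted_rand_score(true, pred)),
    }


def mean_trajectory(group: LabeledDataset, id: str = "mean") -> Trajectory:
    """Pointwise arithmetic mean of a group sharing one time grid.

    This is the barycenter of the group under the flat 1D Euclidean
    distance between value sequences.  For oscillatory groups with random
    phases the mean damps the oscillations — the failure mode that
    motivates shape-aware averaging.
    """
    trajs = list(group)
    if not trajs:
        raise InvalidInputError("empty group")
    ref = trajs[0]
    for t in trajs[1:]:
        if t.points.shape != ref.points.shape:
            raise InvalidInputError("trajectories must share length and dimension")
        if (t.times is None) != (ref.times is None) or (
            t.times is not None and not np.array_equal(t.times, ref.times)
        ):
            raise InvalidInputError("trajectories must share one time grid")
    points = np.mean([t.points for t in trajs], axis=0)
    raw = None
    if all(t.raw_values is not None for t in trajs):
        raw = np.mean([t.raw_values for t in trajs], axis=0)
        # the (t, y) embedding of the mean is the mean of embeddings on a
        # shared grid, so points above remain consistent
    return Trajectory(id=id, points=points, times=ref.times, raw_values=raw)


def averaging_assessment(groups: LabeledDataset, candidate_averages,
                         p: float = 2.0) -> dict:
    """Place candidate 'average' trajectories among labeled groups.

    Joins the data with the candidates, computes the GW_tau distance
    matrix and an MDS embedding, and reports for each candidate its mean
    GW_tau distance to every labeled group and the nearest group.
    Candidates may come from any averaging procedure (pointwise means,
    transport barycenters, ...) — they are treated as plain trajectories.
    """
    candidates = list(candidate_averages)
    if not candidates:
        raise InvalidInputError("no candidate averages supplied")
    combined = LabeledDataset(list(groups) + candidates)
    dm = gw_tau_matrix(combined, p=p)
    emb = mds_embed(dm, dim=2)
    idx = groups.groups()
    K = len(groups)
    rows = []
    for c_off, cand in enumerate(candidates):
        dists = dm.D[K + c_off]
        per_group = {lab: float(np.mean(dists[members]))
                     for lab, members in idx.items()}
        nearest = min(per_group, key=per_group.get)
        rows.append({"candidate_id": cand.id, "nearest_group": nearest,
                     **{f"mean_gw_to_{lab}": v for lab, v in per_group.items()}})
    return {
        "assignments": pd.DataFrame(rows),
        "group_mean_distances": {
            r["candidate_id"]: {
                lab: r[f"mean_gw_to_{lab}"] for lab in idx
            } for r in rows
        },
        "distance_matrix": dm,
        "embedding": emb,
    }
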