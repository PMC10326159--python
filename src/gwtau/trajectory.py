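"""Containers for time series trajectories and labeled collections.

A *trajectory* is an ordered list of points in ``R^d``.  One-dimensional
series ``y = h(t)`` are conventionally embedded in the plane as the curve
``t -> (t, h(t))`` before any arc-length computation; for such series the
raw value sequence is retained separately (``raw_values``) because the
Euclidean and DTW baselines compare raw values, not the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["Trajectory", "LabeledDataset", "as_trajectory"]


@dataclass
class Trajectory:
    """One multivariate time series.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    points : (n, d) ndarray
        Ordered coordinates; the first row is the trajectory start.
    times : (n,) ndarray, optional
        Nondecreasing observation times (seconds or abstract units).
    label : str or int, optional
        Class label, if known.
    raw_values : (n,) ndarray, optional
        Original scalar values for series that were embedded as
        ``(t, y)`` pairs; used by the Euclidean/DTW baselines.
    """

    id: str
    points: np.ndarray
    times: np.ndarray | None = None
    label: str | int | None = None
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        if pts.ndim != 2 or pts.shape[0] < 1:
            raise InvalidInputError(
                f"trajectory {self.id!r}: points must be a non-empty (n, d) array"
            )
        if not np.isfinite(pts).all():
            raise InvalidInputError(
                f"trajectory {self.id!r}: non-finite coordinates"
            )
        self.points = pts
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if t.shape != (pts.shape[0],):
                raise InvalidInputError(
                    f"trajectory {self.id!r}: times length {t.shape} does not "
                    f"match {pts.shape[0]} points"
                )
            if not np.isfinite(t).all():
                raise InvalidInputError(f"trajectory {self.id!r}: non-finite times")
            if np.any(np.diff(t) < 0):
                raise InvalidInputError(f"trajectory {self.id!r}: times decrease")
            self.times = t
        if self.raw_values is not None:
            v = np.asarray(self.raw_values, dtype=float)
            if v.shape != (pts.shape[0],):
                raise InvalidInputError(
                    f"trajectory {self.id!r}: raw_values length mismatch"
                )
            self.raw_values = v

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def ndim(self) -> int:
        """Ambient dimension d of the point coordinates."""
        return self.points.shape[1]

    def baseline_matrix(self) -> np.ndarray:
        """Point matrix used by Euclidean/DTW: raw values when the series
        was a 1D embedding, otherwise the coordinates themselves."""
        if self.raw_values is not None:
            return self.raw_values[:, None]
        return self.points

    def with_points(self, points: np.ndarray) -> "Trajectory":
        """Copy with replaced coordinates (label/times/id preserved)."""
        return replace(self, points=np.asarray(points, dtype=float))


def as_trajectory(obj, id: str | None = None) -> Trajectory:
    """Coerce an array-like or :class:`Trajectory` to a Trajectory."""
    if isinstance(obj, Trajectory):
        return obj
    return Trajectory(id=id if id is not None else "traj", points=np.asarray(obj, dtype=float))


@dataclass
class LabeledDataset:
    """An ordered collection of trajectories with unique ids."""

    trajectories: list[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate trajectory ids: {dup}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.trajectories]

    @property
    def labels(self) -> list:
        return [t.label for t in self.trajectories]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.trajectories[i] for i in indices])

    def groups(self) -> dict:
        """Map label -> list of member indices, in first-seen label order."""
        out: dict = {}
        for i, t in enumerate(self.trajectories):
            out.setdefault(t.label, []).append(i)
        return out

    @staticmethod
    def concat(*parts: "LabeledDataset") -> "LabeledDataset":
        trajs: list[Trajectory] = []
        for part in parts:
            trajs.extend(part.trajectories)
        return LabeledDataset(trajs)
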