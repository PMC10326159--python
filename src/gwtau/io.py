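"""Readers and writers for trajectory tables and distance matrices.

Long format: CSV with columns ``trajectory_id, t, dim_1..dim_k[, label]``,
rows ordered by ``t`` within each trajectory.  One-dimensional series are
by default embedded as planar curves ``(t, y)`` for arc-length purposes
while the raw values are retained for the Euclidean/DTW baselines.

UCR flat format: one series per row, class label in the first field,
values in the remaining fields; times default to 1..N.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .metric import DistanceMatrix
from .trajectory import LabeledDataset, Trajectory

__all__ = [
    "read_long_csv",
    "write_long_csv",
    "read_ucr",
    "read_distance_matrix",
    "write_distance_matrix",
]


def read_long_csv(path, embed_time_for_1d: bool = True) -> LabeledDataset:
    """Read trajectories from a long-format CSV table.

    For single-coordinate tables (only ``dim_1``), points become
    ``(t, y)`` pairs when ``embed_time_for_1d`` and the raw values are
    kept on the trajectory for the baselines.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"trajectory_id", "t"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    dim_cols = sorted(
        [c for c in df.columns if re.fullmatch(r"dim_\d+", c)],
        key=lambda c: int(c.split("_")[1]),
    )
    if not dim_cols:
        raise InvalidInputError(f"{path}: no dim_1..dim_k columns found")
    check_cols = ["t", *dim_cols]
    bad = df.index[df[check_cols].isna().any(axis=1)]
    if len(bad):
        raise InvalidInputError(
            f"{path}: NaN/missing value at data row {int(bad[0]) + 2} "
            "(1-based, counting the header)"
        )
    has_label = "label" in df.columns
    trajs = []
    for tid, sub in df.groupby("trajectory_id", sort=False):
        t = sub["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise InvalidInputError(
                f"{path}: non-monotone t within trajectory {tid!r}"
            )
        coords = sub[dim_cols].to_numpy(dtype=float)
        label = sub["label"].iloc[0] if has_label else None
        if pd.isna(label):
            label = None
        if coords.shape[1] == 1 and embed_time_for_1d:
            y = coords[:, 0]
            trajs.append(Trajectory(str(tid), np.column_stack((t, y)),
                                    times=t, label=label, raw_values=y))
        else:
            trajs.append(Trajectory(str(tid), coords, times=t, label=label))
    return LabeledDataset(trajs)


def write_long_csv(data: LabeledDataset, path) -> None:
    """Write a dataset in long format (1D-embedded series are written back
    as single-coordinate tables, so write -> read round-trips)."""
    frames = []
    has_label = any(t.label is not None for t in data)
    for traj in data:
        coords = (traj.raw_values[:, None] if traj.raw_values is not None
                  else traj.points)
        t = traj.times if traj.times is not None else np.arange(len(coords), dtype=float)
        frame = {"trajectory_id": traj.id, "t": t}
        for k in range(coords.shape[1]):
            frame[f"dim_{k + 1}"] = coords[:, k]
        if has_label:
            frame["label"] = traj.label
        frames.append(pd.DataFrame(frame))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ucr(path, delimiter: str | None = None,
             embed_time_for_1d: bool = True) -> LabeledDataset:
    """Read a UCR-archive flat file: label then values, one series per row."""
    text = Path(path).read_text()
    first = text.splitlines()[0] if text.strip() else ""
    if delimiter is None:
        delimiter = "\t" if "\t" in first else ("," if "," in first else None)
    df = pd.read_csv(_io.StringIO(text), header=None, sep=delimiter or r"\s+",
                     engine="python")
    if df.isna().any().any():
        raise InvalidInputError(f"{path}: ragged rows or missing values")
    labels = df.iloc[:, 0].to_numpy()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    n = values.shape[1]
    t = np.arange(1, n + 1, dtype=float)
    trajs = []
    for i, (lab, y) in enumerate(zip(labels, values)):
        lab = int(lab) if float(lab).is_integer() else lab
        if embed_time_for_1d:
            trajs.append(Trajectory(f"series_{i}", np.column_stack((t, y)),
                                    times=t, label=lab, raw_values=y))
        else:
            trajs.append(Trajectory(f"series_{i}", y[:, None], times=t, label=lab))
    return LabeledDataset(trajs)


def write_distance_matrix(D: DistanceMatrix, path) -> None:
    """Write a distance matrix as CSV with '#'-prefixed metadata lines.

    Entries carry 17 significant digits, enough for a lossless float64
    round trip.
    """
    with open(path, "w") as fh:
        fh.write(f"# metric: {D.metric}\n")
        fh.write(f"# p: {D.p!r}\n")
        fh.write("id," + ",".join(D.ids) + "\n")
        for i, tid in enumerate(D.ids):
            row = ",".join(f"{v:.17g}" for v in D.D[i])
            fh.write(f"{tid},{row}\n")


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a distance matrix written by :func:`write_distance_matrix`."""
    meta = {}
    lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*:\s*(.*)", line)
            if m:
                meta[m.group(1)] = m.group(2).strip().strip("'\"")
        elif line.strip():
            lines.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(lines)), index_col=0,
                     float_precision="round_trip")
    ids = [str(c) for c in df.columns]
    D = df.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1]:
        raise InvalidInputError(f"{path}: matrix is not square")
    if np.max(np.abs(D - D.T), initial=0.0) > 1e-9:
        raise InvalidInputError(f"{path}: matrix asymmetric beyond 1e-9")
    D = (D + D.T) / 2.0
    if np.any(np.diag(D) != 0):
        raise InvalidInputError(f"{path}: nonzero diagonal")
    if np.any(D < 0):
        raise InvalidInputError(f"{path}: negative entries")
    return DistanceMatrix(ids=ids, D=D, metric=meta.get("metric", "unknown"),
                          p=float(meta.get("p", 2.0)))
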