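import numpy as np
import pytest

from gwtau import LabeledDataset, Trajectory


def random_trajectory(rng, n=None, d=None, id="t", scale=1.0, label=None):
    """Random walk trajectory with n points in R^d."""
    n = int(rng.integers(1, 16)) if n is None else n
    d = int(rng.integers(1, 4)) if d is None else d
    pts = np.cumsum(rng.normal(0.0, scale, size=(n, d)), axis=0)
    return Trajectory(id=id, points=pts, label=label)


def random_rotation(rng, d):
    """Haar-uniform rotation matrix via QR with sign fix."""
    q, r = np.linalg.qr(rng.normal(size=(d, d)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_block_distance_matrix():
    """6x6 matrix with two well-separated blocks of three items."""
    D = np.full((6, 6), 10.0)
    for block in (slice(0, 3), slice(3, 6)):
        D[block, block] = 0.1
    np.fill_diagonal(D, 0.0)
    return D


@pytest.fixture
def shared_grid_group():
    t = np.linspace(0.0, 2.0 * np.pi, 50)
    def mk(i, y):
        return Trajectory(f"g{i}", np.column_stack((t, y)), times=t,
                          raw_values=y, label="g")
    return LabeledDataset([mk(0, np.sin(t)), mk(1, np.sin(t + np.pi / 2))])
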