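"""Seeded synthetic trajectory generators.

Four families of benchmark data, each exercising a regime where shape-aware
trajectory comparison matters:

* :func:`gen_shapes` — four analytic unit-speed curves (3D helix, 2D
  circle, 3D line, 2D line) sampled at unequally spaced time points; the
  two "circular" shapes share an arc-length law despite different ambient
  dimensions, as do the two lines.
* :func:`gen_straight_around` — two classes of noisy 3D paths from
  (1, 1, 1) to the origin, distinguished only by *when* a high-variance
  excursion happens (early vs. late): a timing-of-activity signal.
* :func:`gen_lotka_volterra_3d` — a three-species generalized
  Lotka-Volterra system ``dx/dt = diag(x) (r + A x)`` in three parameter
  regimes (stable focus, unstable focus, unstable node) with random
  initial conditions near the relevant steady state.
* :func:`gen_wobble_like` — a 1D oscillatory-angle dataset mimicking
  pronuclear "wobble" measurements in early C. elegans embryos: one flat
  (control-like) class and oscillatory (knockdown-like) classes with
  per-trajectory random phase and amplitude.

All generators are pure functions of their arguments: the same seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import special_ortho_group

from .exceptions import ComputationError, InvalidInputError, InvalidParameterError
from .trajectory import LabeledDataset, Trajectory

__all__ = [
    "gen_shapes",
    "gen_straight_around",
    "LVRegime",
    "DEFAULT_LV_REGIMES",
    "gen_lotka_volterra_3d",
    "random_rotate",
    "gen_wobble_like",
]


def _unequal_grid(rng: np.random.Generator, a: float, b: float, n: int) -> np.ndarray:
    """Sorted uniform random points on [a, b] including both endpoints."""
    if n < 2:
        raise InvalidParameterError("need at least 2 points")
    inner = np.sort(rng.uniform(a, b, size=n - 2))
    return np.concatenate(([a], inner, [b]))


# ---------------------------------------------------------------------------
# analytic shapes
# ---------------------------------------------------------------------------

def gen_shapes(n_line: int = 30, n_circle: int = 500,
               spacing: str = "random-unequal", seed: int = 0) -> LabeledDataset:
    """Four analytic shapes: helix, circle (label 'circle'); two straight
    lines in 3D and 2D (label 'line').

    The circular shapes are sampled on [0, 23*pi/12] and the lines on
    [0, 2].  All four curves are unit speed, so the final cumulative arc
    length approximates the interval length up to polygonal (chord vs.
    arc) error; ``n_circle`` defaults high enough that this error is well
    below 1e-3 for the curved shapes (lines are chord-exact at any n).
    """
    if n_line < 2 or n_circle < 2:
        raise InvalidParameterError("counts must be >= 2")
    rng = np.random.default_rng(seed)
    t_circ_end = 23.0 * np.pi / 12.0

    def grid(a, b, n):
        if spacing == "uniform":
            return np.linspace(a, b, n)
        if spacing == "random-unequal":
            return _unequal_grid(rng, a, b, n)
        raise InvalidParameterError(f"unknown spacing {spacing!r}")

    t1 = grid(0.0, t_circ_end, n_circle)
    t2 = grid(0.0, t_circ_end, n_circle)
    t3 = grid(0.0, 2.0, n_line)
    t4 = grid(0.0, 2.0, n_line)
    s2 = 1.0 / np.sqrt(2.0)
    s3 = 1.0 / np.sqrt(3.0)
    trajs = [
        Trajectory("helix3d", s2 * np.column_stack((np.cos(t1), np.sin(t1), t1)),
                   times=t1, label="circle"),
        Trajectory("circle2d", np.column_stack((np.cos(t2), np.sin(t2))),
                   times=t2, label="circle"),
        Trajectory("line3d", s3 * np.column_stack((t3, t3, t3)),
                   times=t3, label="line"),
        Trajectory("line2d", s2 * np.column_stack((t4, t4)),
                   times=t4, label="line"),
    ]
    return LabeledDataset(trajs)


# backwards-compatible alias matching the figure the dataset emulates
gen_shapes_fig1b = gen_shapes


# ---------------------------------------------------------------------------
# StraightAround
# ---------------------------------------------------------------------------

def gen_straight_around(n_per_class: int = 30, n_points: int = 300,
                        base_noise_sd: float = 0.01,
                        excursion_sd: float = 0.15,
                        excursion_len: int | None = None,
                        seed: int = 0) -> LabeledDataset:
    """Two classes of noisy straight 3D paths with a timed excursion.

    Each trajectory runs from (1, 1, 1) to the origin on a common grid of
    ``n_points`` time instances with small Gaussian coordinate noise
    (``base_noise_sd``).  A window of ``excursion_len`` consecutive points
    receives additional high-variance Gaussian noise (``excursion_sd``);
    the window falls in the first third of the path for class 1 and the
    last third for class 2, so only the *timing* of the excursion carries
    the class signal.  ``excursion_len`` defaults to a fifth of the series
    (60 points at the default length).
    """
    if not (excursion_sd > base_noise_sd > 0):
        raise InvalidParameterError("need excursion_sd > base_noise_sd > 0")
    if excursion_len is None:
        excursion_len = n_points // 5
    if excursion_len > n_points // 3:
        raise InvalidParameterError("excursion window longer than a third of the path")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_points)
    base = (1.0 - t)[:, None] * np.ones(3)[None, :]
    trajs = []
    for cls in (1, 2):
        lo, hi = (0, n_points // 3 - excursion_len) if cls == 1 else (
            2 * n_points // 3, n_points - excursion_len)
        for i in range(n_per_class):
            pts = base + rng.normal(0.0, base_noise_sd, size=(n_points, 3))
            start = int(rng.integers(lo, hi + 1))
            pts[start:start + excursion_len] += rng.normal(
                0.0, excursion_sd, size=(excursion_len, 3))
            trajs.append(Trajectory(f"sa_c{cls}_{i}", pts, times=t, label=cls))
    return LabeledDataset(trajs)


# ---------------------------------------------------------------------------
# 3D Lotka-Volterra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LVRegime:
    """One parameter regime of ``dx/dt = diag(x) (r + A x)``.

    ``equilibrium`` is the steady state near which initial conditions are
    sampled.  Two IC laws are supported (both multiplicative in log
    coordinates, preserving positivity):

    * ``ic_radius`` set (focus regimes): perturbations of fixed magnitude
      ``ic_radius`` at a uniformly random phase in the oscillation plane
      (plus a small random out-of-plane component), so class members are
      phase-shifted versions of one another;
    * ``ic_radius`` None (node regime): isotropic lognormal spread with
      log-sd ``ic_log_sd``.
    """

    name: str
    r: tuple
    A: tuple
    equilibrium: tuple
    ic_radius: float | None = None
    ic_log_sd: float = 0.1

    def jacobian_at_equilibrium(self) -> np.ndarray:
        """Jacobian of the vector field at the regime's named equilibrium:
        ``diag(x*) A + diag(r + A x*)`` (the second term vanishes at an
        interior steady state); at the origin this reduces to ``diag(r)``."""
        A = np.asarray(self.A, dtype=float)
        r = np.asarray(self.r, dtype=float)
        x = np.asarray(self.equilibrium, dtype=float)
        return np.diag(x) @ A + np.diag(r + A @ x)


def _interior_regime(name, A, ic_radius):
    A = np.array(A, dtype=float)
    r = -A @ np.ones(3)
    return LVRegime(name=name, r=tuple(r), A=tuple(map(tuple, A)),
                    equilibrium=(1.0, 1.0, 1.0), ic_radius=ic_radius)


#: shipped default regimes: interaction matrices chosen so that the
#: linearization at the named steady state has the stated character
#: (verified by the Jacobian eigenvalue tests).  The focus regimes keep
#: the oscillation in the first two species (block-structured A) with the
#: third species fast and stable.
DEFAULT_LV_REGIMES = {
    1: _interior_regime(  # stable focus at (1,1,1): eigs -0.2 +/- i, -0.8
        "stable_focus",
        [[-0.2, -1.0, 0.0], [1.0, -0.2, 0.0], [0.0, 0.0, -0.8]],
        ic_radius=0.1),
    2: _interior_regime(  # unstable focus at (1,1,1): eigs 0.08 +/- i, -0.8
        "unstable_focus",
        [[0.08, -1.0, 0.0], [1.0, 0.08, 0.0], [0.0, 0.0, -0.8]],
        ic_radius=0.05),
    3: LVRegime(  # unstable node at the origin: Jacobian diag(r) > 0
        name="unstable_node",
        r=(0.9, 1.0, 1.1),
        A=((-1.0, -0.1, -0.1), (-0.1, -1.0, -0.1), (-0.1, -0.1, -1.0)),
        equilibrium=(0.0, 0.0, 0.0),
        ic_radius=None,
        ic_log_sd=0.3),
}

#: base point for initial conditions near the origin regime
_ORIGIN_IC_SCALE = 0.05
#: out-of-plane log-perturbation sd relative to ic_radius (focus regimes)
_IC_OUT_OF_PLANE = 0.3


def gen_lotka_volterra_3d(n_per_class: int = 20, n_points: int = 1000,
                          t_max: float = 30.0,
                          regimes: dict | None = None,
                          seed: int = 0, max_retries: int = 5) -> LabeledDataset:
    """Three classes of 3D generalized Lotka-Volterra solution trajectories.

    For each regime, initial conditions are sampled near the regime's
    steady state (near a small positive point for the origin regime)
    following the regime's IC law, and the system is integrated in log
    coordinates
    (``u = log x``, ``du/dt = r + A exp(u)``), which keeps every
    coordinate strictly positive by construction.  Output is sampled on a
    fixed grid of ``n_points`` times in [0, t_max].  A solution whose log
    coordinates leave [-20, 20] (blow-up or collapse) is regenerated with
    a fresh initial condition up to ``max_retries`` times.
    """
    regimes = DEFAULT_LV_REGIMES if regimes is None else regimes
    rng = np.random.default_rng(seed)
    t_eval = np.linspace(0.0, t_max, n_points)
    trajs = []
    for cls, regime in sorted(regimes.items()):
        r = np.asarray(regime.r, dtype=float)
        A = np.asarray(regime.A, dtype=float)
        eq = np.asarray(regime.equilibrium, dtype=float)
        center = eq if eq.min() > 0 else np.full(3, _ORIGIN_IC_SCALE)

        def rhs(t, u):
            return r + A @ np.exp(u)

        def sample_ic():
            if regime.ic_radius is not None:
                theta = rng.uniform(0.0, 2.0 * np.pi)
                eta = rng.normal(0.0, _IC_OUT_OF_PLANE)
                pert = regime.ic_radius * np.array(
                    [np.cos(theta), np.sin(theta), eta])
            else:
                pert = rng.normal(0.0, regime.ic_log_sd, size=3)
            return center * np.exp(pert)

        for i in range(n_per_class):
            for attempt in range(max_retries + 1):
                x0 = sample_ic()
                sol = solve_ivp(rhs, (0.0, t_max), np.log(x0), t_eval=t_eval,
                                rtol=1e-8, atol=1e-10, method="RK45")
                if sol.success and np.abs(sol.y).max() < 20.0:
                    break
            else:
                raise ComputationError(
                    f"LV regime {regime.name}: integration kept failing "
                    f"after {max_retries} retries")
            pts = np.exp(sol.y.T)
            trajs.append(Trajectory(f"lv_c{cls}_{i}", pts, times=t_eval,
                                    label=cls))
    return LabeledDataset(trajs)


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

def random_rotate(data: LabeledDataset, per_trajectory: bool = True,
                  seed: int = 0) -> LabeledDataset:
    """Apply Haar-uniform random 3D rotations to a dataset.

    One independent rotation per trajectory when ``per_trajectory``, else a
    single shared rotation.  Arc lengths — hence GW_tau — are unchanged;
    coordinate-based distances (Euclidean, DTW) generally are not.
    """
    rng = np.random.default_rng(seed)
    if any(t.ndim != 3 for t in data):
        raise InvalidInputError("random_rotate requires 3D trajectories")
    shared = None if per_trajectory else special_ortho_group.rvs(3, random_state=rng)
    out = []
    for t in data:
        R = special_ortho_group.rvs(3, random_state=rng) if per_trajectory else shared
        out.append(t.with_points(t.points @ R.T))
    return LabeledDataset(out)


# ---------------------------------------------------------------------------
# Wobble-like oscillatory angles
# ---------------------------------------------------------------------------

def gen_wobble_like(n_flat: int = 10, n_osc=(12, 7), n_points: int = 40,
                    dt: float = 5.0, amplitude: float = 30.0,
                    frequency: float = 0.02,
                    phase_jitter=(2.0 * np.pi, 0.5),
                    drift_sd: float = 0.01, noise_sd: float = 2.0,
                    seed: int = 0) -> LabeledDataset:
    """1D oscillatory-angle dataset emulating pronuclear wobble series.

    One flat class ("EV", control-like): small linear drift plus noise.
    ``len(n_osc)`` oscillatory classes ("RNAi1", "RNAi2", ...): sinusoids
    ``A_j sin(2 pi f t + phi_j)`` with per-trajectory amplitude
    (lognormal around ``amplitude``, in degrees) and random phase drawn
    uniformly from [0, phase_jitter[c]) — the first oscillatory class is
    fully phase-jittered by default, the second only mildly.

    All series share one grid of ``n_points`` points spaced ``dt`` seconds
    apart.  Each series is stored with its raw angle values and with the
    planar ``(t, y)`` embedding used for arc-length profiles.
    """
    if min(n_points, n_flat) < 1 or dt <= 0 or amplitude <= 0 or frequency <= 0:
        raise InvalidParameterError("parameters must be positive")
    n_osc = tuple(n_osc)
    jit = tuple(phase_jitter)
    if len(jit) != len(n_osc):
        raise InvalidParameterError("phase_jitter must match n_osc length")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt
    trajs = []

    def make(id_, y, label):
        pts = np.column_stack((t, y))
        trajs.append(Trajectory(id_, pts, times=t, label=label, raw_values=y))

    for i in range(n_flat):
        a0 = rng.normal(0.0, 2.0)
        slope = rng.normal(0.0, drift_sd)
        y = a0 + slope * t + rng.normal(0.0, noise_sd, size=n_points)
        make(f"EV_{i}", y, "EV")
    for c, (n_c, jc) in enumerate(zip(n_osc, jit), start=1):
        label = f"RNAi{c}"
        for i in range(n_c):
            amp = amplitude * np.exp(rng.normal(0.0, 0.15))
            phi = rng.uniform(0.0, jc)
            y = amp * np.sin(2.0 * np.pi * frequency * t + phi)
            y += rng.normal(0.0, noise_sd, size=n_points)
            make(f"{label}_{i}", y, label)
    return LabeledDataset(trajs)
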