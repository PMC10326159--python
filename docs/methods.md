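# Methods

## The distance

A discrete trajectory is an ordered list of points x_1, …, x_n in R^d.  It
is viewed as a metric-measure space: the metric is the intrinsic polygonal
arc length (the distance between x_i and x_j is the length of the polygonal
arc between them along the trajectory), and the measure is uniform, 1/n per
point.  A 1D series y = h(t) is first embedded as the planar curve
t ↦ (t, h(t)), so that the "speed" of a scalar series combines drift in
time and change in value; 2D/3D series are used as-is.

Fixing the first argument of the intrinsic metric at the start point r_X
yields the distance-from-start profile v_k = Σ_{j<k} ‖x_{j+1} − x_j‖, a
nondecreasing vector starting at 0.  GW_τ between trajectories X and Y with
exponent p ∈ [1, ∞) is the p-Wasserstein distance between the two profile
distributions (each profile value carrying its point's mass).  Key
consequences:

- **Closed form.**  On the real line the Wasserstein distance is the
  L^p distance between quantile functions.  Equal sizes n = m = N with
  uniform weights: W_p^p = (1/N) Σ |z_i − w_i|^p over sorted supports —
  and profiles are sorted by construction, so the evaluation is a single
  O(N) pass with no sort (asserted, never applied).  Unequal sizes: the
  quantile coupling λ_ij = (i/n ∧ j/m − (i−1)/n ∨ (j−1)/m)₊, evaluated
  along its staircase support of ≤ n + m − 1 entries (identical value to
  the full n×m double sum; ties on the staircase are resolved by exact
  integer cross-multiplication i·m vs j·n).  Non-uniform weights: the
  quantile integral over merged CDF breakpoints, evaluated at interval
  midpoints to avoid boundary ambiguity.
- **Invariances.**  Profiles depend only on inter-point Euclidean
  distances, so GW_τ is invariant under rotations, translations and
  reflections applied to either trajectory independently, and compares
  trajectories of different ambient dimensions and lengths.
- **Pseudo-metric.**  Trajectories with the same distribution of
  distances from the start are indistinguishable — e.g. a curve and its
  mirror image, or any two unit-speed curves on the same parameter
  interval.  GW_τ is a true metric on the space of profile distributions.
- **Bound.**  GW_τ upper-bounds the Gromov–Wasserstein distance GW, and
  Mémoli's Third Lower Bound gives TLB ≤ GW ≤ GW_τ, which the package
  verifies numerically.

Assumptions worth keeping in mind: the underlying continuous curve is
assumed injective and continuously differentiable; repeated consecutive
points (zero-length segments) violate injectivity and are allowed with a
warning — the profile stays nondecreasing.  A single-point trajectory has
profile [0]; its GW_τ to any other trajectory is the p-mean of the other
profile.

## Parameters

- `p` (default 2, dimensionless): Wasserstein exponent.  All the shipped
  workflows use p = 2; any p ≥ 1 is accepted, and W_p is nondecreasing in
  p for fixed profiles.
- 1-NN tie-breaking: lowest training index (the common archive-benchmark
  convention).
- k-medoids (`KMedoids`): PAM-style alternation with 50 seeded random
  restarts by default; the lowest-cost restart wins.  The variant used in
  the original analyses is unstated, so determinism and simplicity decided.
- MDS: classical (Torgerson) scaling — deterministic (no seed), exact for
  Euclidean-realizable matrices; eigenvalue diagnostics are exposed.  The
  full spectrum indicates how much of the distance structure is planar.
- Euclidean/DTW baselines compare scalar series on raw values; GW_τ uses
  the (t, y) embedding.  This asymmetry is deliberate: it follows each
  distance's standard convention.  DTW dialect: unconstrained, steps
  (1,0), (0,1), (1,1), Euclidean local cost, summed along the path.
  For UCR-style inputs t defaults to the index 1..N; no z-normalization is
  applied by default (`embed_time_for_1d` and reader options control this).

## Synthetic data

The generators reproduce the statistical structure of the study datasets
so every claim is testable without downloads.  All are pure functions of
their configuration; the same seed gives byte-identical data.

- **Analytic shapes** (`gen_shapes`): helix (1/√2)(cos t, sin t, t) and
  circle (cos t, sin t) on [0, 23π/12]; lines (1/√3)(t, t, t) and
  (1/√2)(t, t) on [0, 2]; unequal spacing drawn as sorted uniforms with
  endpoints.  All four are unit speed, so the final profile value should
  equal the interval length up to chord-vs-arc error ≈ Σ κ²θ³/24 over the
  gaps.  Defaults n_circle = 500, n_line = 30: lines are chord-exact at
  any sampling, while the curved shapes need ~hundreds of points for the
  polygonal error to sit comfortably below 1e−3 at random spacing (at ~50
  points it is a few 1e−3).
- **StraightAround** (`gen_straight_around`): 60 trajectories of 300
  points in 3D from (1,1,1) to the origin, coordinate noise sd 0.01, plus
  a 60-point window of excursion noise sd 0.15 placed randomly in the
  first third (class 1) or last third (class 2).  Noise scales are design
  choices (unprinted in the source analyses) sized so the excursion
  dominates the base noise but not the path.  The class signal is purely
  *when* extra path length is accrued.
- **3D Lotka–Volterra** (`gen_lotka_volterra_3d`): dx/dt = diag(x)(r + Ax)
  with three shipped regimes: stable focus at (1,1,1) (Jacobian
  eigenvalues −0.2 ± i, −0.8), unstable focus at (1,1,1) (0.08 ± i, −0.8),
  and unstable node at the origin (diag(0.9, 1.0, 1.1)), each verified by
  eigenvalue tests; the exact parameter values of the original model were
  unavailable, so the regimes are this package's own realization of the
  three stated local behaviors, and any transcription of the original
  parameters can be passed via the `regimes` argument.  Initial conditions
  for the focus regimes are fixed-radius (0.1 and 0.05 in log coordinates)
  random-phase perturbations in the oscillation plane, making class
  members phase-shifted relatives — the within-class variability the
  method is designed to absorb; the node regime uses lognormal spread
  around a small positive point.  Integration is in log coordinates
  (u = log x, du/dt = r + A e^u), which enforces positivity exactly;
  solutions leaving |u| < 20 are regenerated with fresh initial conditions
  up to a retry cap.  Default 20 trajectories/class × 1000 points over
  t ∈ [0, 30]; the shipped robustness analyses use 10/class × 200 points
  to keep the full pipeline fast.
- **Rotations** (`random_rotate`): Haar-uniform SO(3) rotations, shared or
  per-trajectory, labels preserved.
- **Wobble-like** (`gen_wobble_like`): 1D angle series on 40 points at
  5 s spacing — 10 flat control-like traces (drift + noise, sd 2°), and
  12 + 7 oscillatory traces A_j sin(2πf t + φ_j) with amplitude lognormal
  around 30° (sd 0.15 in log), f = 0.02 Hz (≈ 4 cycles per trace), and
  phase φ_j uniform on [0, 2π) for the first oscillatory class and
  [0, 0.5) for the second.  Group sizes and the time grid match the
  published experimental design; amplitudes/frequencies are realistic
  stand-ins for pronuclear wobble.  The fully jittered class exists to
  demonstrate the averaging failure mode: its pointwise mean damps the
  oscillation (phase averaging) and is placed by GW_τ near the flat group.

What passing tests on these data do **not** show: performance on real
recordings with measurement artifacts, missing samples, baseline drift or
heavy-tailed noise; none of the generators emulates those.  The readers
accept real long-CSV/UCR data so such analyses can be run when files are
supplied, but no downloaded dataset is part of the test surface.

## Numerical choices

- Profile values are left-to-right double-precision cumulative sums; they
  are order-dependent floating-point sums, documented as such.
- Probability-vector checks at 1e−12 (profiles, couplings); LP oracle
  accepts weights within 1e−9 of normalization.
- The transport LPs (oracle, TLB outer program) are solved exactly with
  HiGHS on sparse marginal constraints (the redundant last column
  constraint is dropped); intended for n·m up to ~10⁴ variables — these
  are validators, not fast paths.  Local distance distributions are not
  monotone, so the TLB cost matrix sorts supports first (O(N log N) per
  anchor pair).
- Classical MDS clips negative eigenvalues to zero and fixes signs so the
  largest-magnitude loading of each axis is positive (deterministic up to
  exactly reproducible output).
- Distance-matrix CSV round-trips at 17 significant digits; readers parse
  with exact (round-trip) float precision and reject asymmetry beyond
  1e−9, negative entries, and nonzero diagonals.

## Known limitations

- GW_τ ignores time stamps once the embedding is fixed: series that
  traverse the same path at different speeds but identical point layouts
  are indistinguishable, as are mirror images.
- DTW here is the unconstrained textbook dialect; windowed or derivative
  variants are out of scope.
- The TLB implementation follows the cited construction as an exact LP;
  it is quadratic in the number of anchor pairs and meant for small
  trajectories.
- The full GW program (non-convex quadratic) is deliberately not solved;
  GW is only bracketed by TLB and GW_τ.
- Statistical inference on GW_τ (confidence statements about population
  distances) is not implemented.
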