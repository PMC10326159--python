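# gwtau

Shape-aware comparison of time series via a scalable Gromov–Wasserstein-type
distance.

## The problem

Biological time series — pronuclear-angle traces in *C. elegans* embryos,
ECG heartbeats, simulated population dynamics — often need to be compared by
*shape*: two oscillatory traces that differ only in phase should be close,
while a flat trace should be far from both.  Coordinate-wise distances
(Euclidean, and to a lesser degree dynamic time warping) struggle with phase
shifts, rotations of the ambient space, and series of different lengths or
dimensions.

`gwtau` implements **GW_τ**, a distance that treats each trajectory as its
own metric-measure space.  A trajectory
X = {x_1, …, x_n} ⊂ R^d carries the intrinsic polygonal arc-length metric
d_X and the uniform measure μ_X = Σᵢ δ_{x_i}/n.  Fixing one argument of
d_X at the start point r_X = x_1 gives the *distance-from-start* profile,
and

  GW_τ(X, Y) = W_p( d_X(r_X,·)_# μ_X , d_Y(r_Y,·)_# μ_Y ),

the p-Wasserstein distance between the pushforward measures of the two
profiles on the real line.  On the line W_p has a closed form: with uniform
weights and equal lengths n = m = N it is the order-statistics pairing

  W_p^p = (1/N) Σᵢ |z_i − w_i|^p,

and because cumulative arc lengths are *already sorted*, GW_τ costs O(N)
— no optimization, no sort.  For unequal lengths the quantile
(north-west-corner) coupling λ_ij = (i/n ∧ j/m − (i−1)/n ∨ (j−1)/m)₊ gives
the optimum with at most n + m − 1 nonzero terms.  GW_τ upper-bounds the
full Gromov–Wasserstein distance, is invariant to rigid motions of either
trajectory, and compares series of different ambient dimensions directly.
It is a pseudo-metric on trajectories (a metric on profile space): a curve
and its mirror image are indistinguishable.

The package also ships:

- Mémoli's **Third Lower Bound (TLB)** and an exact LP Wasserstein oracle,
  so TLB ≤ GW ≤ GW_τ can be checked numerically;
- **Euclidean** and unconstrained **DTW** baselines (numba DP kernel, with
  operation counters);
- the downstream workflow: 1-NN classification, PAM k-medoids and
  single/complete-linkage clustering on precomputed matrices, classical
  MDS embedding with k-means, partition scoring, and assessment of
  trajectory-averaging procedures;
- seeded synthetic generators (analytic shapes, excursion-timing classes,
  a three-regime 3D Lotka–Volterra system with random 3D rotations, and an
  oscillatory-angle "wobble" dataset);
- plain-text I/O (long CSV, UCR flat files, distance-matrix CSV) and a
  `gwtau` command-line tool.

Everything is exposed both as sklearn-style estimators
(`GWTau().fit(train).transform(test)` → cross-distance matrix, `KMedoids`,
`ClassicalMDS`, `OneNearestNeighbor`) and as plain functions.

## Worked example

Four analytic curves — a 3D helix and a 2D circle (both unit-speed on
[0, 23π/12]), and 3D/2D straight lines on [0, 2] — sampled at unequally
spaced points:

```python
import numpy as np
from gwtau import gen_shapes, gw_tau_matrix

shapes = gen_shapes(seed=0)
D = gw_tau_matrix(shapes, p=2)
print(D.ids)
print(np.array_str(D.D, precision=3, suppress_small=True))
```

```
['helix3d', 'circle2d', 'line3d', 'line2d']
[[0.    0.18  2.646 2.659]
 [0.18  0.    2.487 2.505]
 [2.646 2.487 0.    0.241]
 [2.659 2.505 0.241 0.   ]]
```

The helix and the circle live in different dimensions and are sampled at
different points, yet their shared arc-length law makes them close (0.18);
likewise the two lines (0.24).  Every curve-vs-line distance is an order of
magnitude larger (≈ 2.5): the matrix has the two-block structure a
shape-aware distance should produce.

Clustering an oscillatory-angle dataset (10 flat control-like traces, 12 + 7
oscillatory traces with random phases) recovers the flat/oscillatory split
exactly:

```python
from gwtau import (gen_wobble_like, gw_tau_matrix, kmedoids_cluster,
                   clustering_quality)
data = gen_wobble_like(seed=0)
D = gw_tau_matrix(data, p=2)
pred = kmedoids_cluster(D, k=2, seed=0)
truth = ["flat" if t.label == "EV" else "osc" for t in data]
print(clustering_quality(pred, truth))
```

```
{'error_count': 0, 'ari': 1.0}
```

The same pipeline runs from the shell:

```sh
gwtau simulate wobble --seed 0 --out data.csv
gwtau dist --input data.csv --format long --metric gwtau --p 2 --out D.csv
gwtau cluster --distances D.csv --method kmedoids --k 2 --seed 0 --out labels.csv
gwtau embed --distances D.csv --dim 2 --out coords.csv
```

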