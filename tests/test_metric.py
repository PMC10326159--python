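"""Core distance: arc-length profiles, quantile coupling, closed-form
1D Wasserstein, and the GW_tau distance itself."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gwtau
from gwtau import (
    DistanceProfile,
    InternalInvariantError,
    InvalidInputError,
    InvalidParameterError,
    LabeledDataset,
    Trajectory,
    cumulative_arclength,
    gw_tau,
    gw_tau_matrix,
    quantile_coupling_weights,
    wasserstein_1d,
    wasserstein_1d_lp_oracle,
)
from conftest import random_rotation, random_trajectory

SETTINGS = dict(deadline=None, derandomize=True, max_examples=60)


# ---------------------------------------------------------------------------
# cumulative arc length
# ---------------------------------------------------------------------------

class TestCumulativeArclength:
    def test_single_point_profile_is_zero(self):
        prof = cumulative_arclength(Trajectory("p", np.zeros((1, 2))))
        assert prof.values.tolist() == [0.0]
        assert prof.weights.tolist() == [1.0]

    def test_polygonal_sum_of_segment_norms(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 9.0]])
        prof = cumulative_arclength(Trajectory("p", pts))
        np.testing.assert_allclose(prof.values, [0.0, 5.0, 10.0])

    def test_unit_speed_helix_profile_matches_parameter(self):
        # (cos t, sin t, t)/sqrt(2) has unit speed, so the arc length from
        # the start equals the elapsed parameter up to chord error
        t = np.arange(0.0, 2.0 + 1e-12, 0.01)
        pts = np.column_stack((np.cos(t), np.sin(t), t)) / np.sqrt(2.0)
        prof = cumulative_arclength(Trajectory("helix", pts))
        assert np.max(np.abs(prof.values - t)) < 1e-4

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(InvalidInputError):
            Trajectory("bad", np.array([[0.0], [np.nan]]))

    def test_repeated_points_warn_but_stay_monotone(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.warns(UserWarning, match="repeated"):
            prof = cumulative_arclength(Trajectory("rep", pts))
        assert np.all(np.diff(prof.values) >= 0)

    def test_timestamps_do_not_enter_arc_length(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        a = Trajectory("a", pts, times=np.array([0.0, 1.0]))
        b = Trajectory("b", pts, times=np.array([0.0, 100.0]))
        np.testing.assert_array_equal(
            cumulative_arclength(a).values, cumulative_arclength(b).values
        )


# ---------------------------------------------------------------------------
# quantile coupling
# ---------------------------------------------------------------------------

class TestQuantileCoupling:
    def test_equal_sizes_is_scaled_identity(self):
        lam = quantile_coupling_weights(3, 3).lam
        np.testing.assert_allclose(lam, np.eye(3) / 3.0)

    def test_two_by_three_overlap_lengths(self):
        lam = quantile_coupling_weights(2, 3).lam
        expected = np.array([[1 / 3, 1 / 6, 0.0], [0.0, 1 / 6, 1 / 3]])
        np.testing.assert_allclose(lam, expected)

    def test_single_source_spreads_uniformly(self):
        lam = quantile_coupling_weights(1, 4).lam
        np.testing.assert_allclose(lam, np.full((1, 4), 0.25))

    @given(n=st.integers(1, 12), m=st.integers(1, 12))
    @settings(**SETTINGS)
    def test_marginals_and_staircase_support(self, n, m):
        c = quantile_coupling_weights(n, m)
        np.testing.assert_allclose(c.lam.sum(axis=1), np.full(n, 1 / n),
                                   atol=1e-12)
        np.testing.assert_allclose(c.lam.sum(axis=0), np.full(m, 1 / m),
                                   atol=1e-12)
        assert abs(c.lam.sum() - 1.0) < 1e-12
        assert np.count_nonzero(c.lam) <= n + m - 1
        # monotone (staircase) support
        support = np.argwhere(c.lam > 0)
        order = np.lexsort((support[:, 1], support[:, 0]))
        assert np.all(np.diff(support[order][:, 1]) >= 0)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(InvalidParameterError):
            quantile_coupling_weights(0, 3)


# ---------------------------------------------------------------------------
# 1D Wasserstein closed form
# ---------------------------------------------------------------------------

def _prof(values, weights=None):
    return DistanceProfile(values=np.asarray(values, float), weights=weights)


class TestWasserstein1D:
    def test_identical_measures_zero(self):
        for p in (1.0, 2.0, 3.5):
            assert wasserstein_1d(_prof([0, 1, 2]), _prof([0, 1, 2]), p) == 0.0

    @pytest.mark.parametrize("p,expected", [(1.0, 1.0), (2.0, np.sqrt(5 / 3))])
    def test_equal_size_closed_form(self, p, expected):
        d = wasserstein_1d(_prof([0, 1, 2]), _prof([0, 2, 4]), p)
        assert d == pytest.approx(expected, abs=1e-12)

    def test_unequal_size_staircase(self):
        d = wasserstein_1d(_prof([0, 1]), _prof([0, 1, 2]), p=1)
        assert d == pytest.approx(0.5, abs=1e-12)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(InvalidParameterError):
            wasserstein_1d(_prof([0, 1]), _prof([0, 1]), p=0.5)

    def test_non_monotone_support_is_internal_error(self):
        with pytest.raises(InternalInvariantError):
            DistanceProfile(values=np.array([0.0, 2.0, 1.0]))

    def test_nonuniform_weights_quantile_integral_matches_lp(self, rng):
        for _ in range(20):
            n, m = rng.integers(2, 9, size=2)
            zv = np.concatenate(([0.0], np.sort(rng.uniform(0, 5, n - 1))))
            wv = np.concatenate(([0.0], np.sort(rng.uniform(0, 5, m - 1))))
            zw = rng.dirichlet(np.ones(n))
            ww = rng.dirichlet(np.ones(m))
            # guard against zero weights from dirichlet rounding
            zw = (zw + 1e-6) / (zw + 1e-6).sum()
            ww = (ww + 1e-6) / (ww + 1e-6).sum()
            p = float(rng.choice([1.0, 2.0, 3.0]))
            closed = wasserstein_1d(_prof(zv, zw), _prof(wv, ww), p)
            lp = wasserstein_1d_lp_oracle(zv, zw, wv, ww, p)
            assert closed == pytest.approx(lp, abs=1e-8)

    def test_equal_and_unequal_paths_agree_for_equal_sizes(self, rng):
        # route the same uniform profiles through Eq.11-style pairing and
        # the staircase double sum; they must agree to double precision
        from gwtau.metric import _staircase, _w1d_sorted_uniform
        for _ in range(50):
            n = int(rng.integers(1, 20))
            z = np.concatenate(([0.0], np.sort(rng.uniform(0, 10, n - 1))))
            w = np.concatenate(([0.0], np.sort(rng.uniform(0, 10, n - 1))))
            for p in (1.0, 2.0, 3.0):
                paired = _w1d_sorted_uniform(z, w, p)
                stair = sum(mass * abs(z[i] - w[j]) ** p
                            for i, j, mass in _staircase(n, n))
                assert paired == pytest.approx(stair, abs=1e-12)

    def test_p_monotonicity(self, rng):
        for _ in range(20):
            n, m = rng.integers(1, 12, size=2)
            z = np.concatenate(([0.0], np.sort(rng.uniform(0, 3, n - 1))))
            w = np.concatenate(([0.0], np.sort(rng.uniform(0, 3, m - 1))))
            ds = [wasserstein_1d(_prof(z), _prof(w), p)
                  for p in (1.0, 1.5, 2.0, 3.0, 4.0)]
            assert all(b >= a - 1e-12 for a, b in zip(ds, ds[1:]))


# ---------------------------------------------------------------------------
# GW_tau
# ---------------------------------------------------------------------------

class TestGWTau:
    def test_self_distance_zero(self, rng):
        for _ in range(5):
            a = random_trajectory(rng)
            assert gw_tau(a, a) == 0.0

    def test_two_segment_lines_closed_form(self):
        a = Trajectory("a", np.array([[0.0, 0.0], [1.0, 0.0]]))
        b = Trajectory("b", np.array([[0.0, 0.0], [3.0, 0.0]]))
        # profiles [0,1] vs [0,3]: sqrt((0 + 4)/2)
        assert gw_tau(a, b, p=2) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_cross_dimension_identical_arclength_law(self):
        a = Trajectory("a", np.array([[0, 0], [1, 0], [2, 0]], float))
        b = Trajectory("b", np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float))
        assert gw_tau(a, b) == 0.0

    def test_symmetry_exact(self, rng):
        for _ in range(10):
            a = random_trajectory(rng, id="a")
            b = random_trajectory(rng, id="b")
            assert gw_tau(a, b) == gw_tau(b, a)

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(50):
            a, b, c = (random_trajectory(rng, id=i) for i in "abc")
            for p in (1.0, 2.0):
                assert gw_tau(a, c, p) <= gw_tau(a, b, p) + gw_tau(b, c, p) + 1e-10

    def test_rigid_motion_invariance(self, rng):
        for _ in range(10):
            a = random_trajectory(rng, d=3, n=12)
            R = random_rotation(rng, 3)
            moved = a.with_points(a.points @ R.T + rng.normal(size=3))
            assert gw_tau(a, moved) < 1e-9
            reflected = a.with_points(a.points * np.array([-1.0, 1.0, 1.0]))
            assert gw_tau(a, reflected) < 1e-9

    def test_mirror_image_is_indistinguishable(self):
        # pseudo-metric on trajectories: same distance-from-start law
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.5]])
        mirror = pts * np.array([1.0, -1.0])
        assert gw_tau(Trajectory("a", pts), Trajectory("b", mirror)) == 0.0

    def test_coordinate_scaling_law(self, rng):
        a = random_trajectory(rng, d=2, n=10)
        z = cumulative_arclength(a).values
        p = 2.0
        base = (np.mean(z ** p)) ** (1 / p)
        for s in (0.5, 1.0, 1.7, 3.0):
            d = gw_tau(a, a.with_points(s * a.points), p=p)
            assert d == pytest.approx(abs(s - 1.0) * base, rel=1e-10, abs=1e-12)

    def test_single_point_against_any_is_p_mean_of_profile(self, rng):
        a = Trajectory("pt", np.zeros((1, 3)))
        b = random_trajectory(rng, d=3, n=7)
        z = cumulative_arclength(b).values
        for p in (1.0, 2.0, 3.0):
            assert gw_tau(a, b, p) == pytest.approx(
                np.mean(z ** p) ** (1 / p), rel=1e-12)

    def test_matrix_symmetric_zero_diagonal(self, rng):
        data = LabeledDataset(
            [random_trajectory(rng, id=f"t{i}") for i in range(6)])
        dm = gw_tau_matrix(data)
        assert np.array_equal(dm.D, dm.D.T)
        assert np.all(np.diag(dm.D) == 0)
        assert dm.D[0, 1] == gw_tau(data[0], data[1])

    def test_matrix_of_identical_trajectories_is_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        data = LabeledDataset([Trajectory(f"t{i}", pts) for i in range(4)])
        assert np.all(gw_tau_matrix(data).D == 0.0)

    def test_duplicate_ids_rejected(self):
        pts = np.zeros((2, 2))
        with pytest.raises(InvalidInputError):
            LabeledDataset([Trajectory("x", pts), Trajectory("x", pts)])

    def test_op_count_scales_linearly_for_equal_lengths(self, rng):
        a = random_trajectory(rng, n=100, d=2, id="a")
        b = random_trajectory(rng, n=100, d=2, id="b")
        _, ops_small = gw_tau(a, b, return_ops=True)
        a2 = random_trajectory(rng, n=400, d=2, id="a2")
        b2 = random_trajectory(rng, n=400, d=2, id="b2")
        _, ops_big = gw_tau(a2, b2, return_ops=True)
        assert ops_big / ops_small == pytest.approx(4.0, rel=0.05)
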