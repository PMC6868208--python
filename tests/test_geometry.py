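"""Proximity/spatial metric unit tests and brute-force oracle checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shoalstress import geometry
from shoalstress.geometry import (
    DegenerateFrameError,
    InsufficientFishError,
    OutsideTankError,
    TankGeometry,
)

from conftest import random_frame

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def brute_distance_matrix(xy: np.ndarray) -> np.ndarray:
    n = len(xy)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
    return out


class TestPairwiseDistances:
    def test_pythagorean_pair(self):
        d = geometry.pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(5.0)

    def test_symmetry_and_zero_diagonal(self, rng):
        d = geometry.pairwise_distances(random_frame(rng))
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0)

    def test_matches_loop_oracle(self, rng):
        xy = random_frame(rng)
        assert np.allclose(
            geometry.pairwise_distances(xy), brute_distance_matrix(xy),
            rtol=1e-12, atol=0,
        )

    def test_rejects_single_fish_and_nonfinite(self):
        with pytest.raises(InsufficientFishError, match="insufficient fish"):
            geometry.pairwise_distances(np.array([[1.0, 1.0]]))
        with pytest.raises(ValueError):
            geometry.pairwise_distances(np.array([[0.0, 0.0], [np.nan, 1.0]]))


class TestNearestNeighbour:
    def test_unit_square_all_one(self):
        assert np.allclose(geometry.nearest_neighbour_distances(UNIT_SQUARE), 1.0)

    def test_collinear_hand_geometry(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        assert np.allclose(
            geometry.nearest_neighbour_distances(xy), [1.0, 1.0, 2.0]
        )

    def test_matches_rowwise_min_oracle(self, rng):
        xy = random_frame(rng)
        d = brute_distance_matrix(xy)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(
            geometry.nearest_neighbour_distances(xy), d.min(axis=1)
        )


class TestCvNearestNeighbour:
    def test_zero_variance(self):
        assert geometry.cv_nearest_neighbour(UNIT_SQUARE) == pytest.approx(0.0)

    def test_hand_computed_sample_sd(self):
        # NND vector [1, 1, 2]: mean 4/3, sample sd sqrt(1/3)
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        expected = np.sqrt(1.0 / 3.0) / (4.0 / 3.0)
        assert geometry.cv_nearest_neighbour(xy) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.4330, abs=5e-5)

    def test_scale_invariance(self, rng):
        xy = random_frame(rng)
        assert geometry.cv_nearest_neighbour(3.7 * xy) == pytest.approx(
            geometry.cv_nearest_neighbour(xy), rel=1e-9
        )

    def test_coincident_fish_raise(self):
        with pytest.raises(DegenerateFrameError, match="degenerate"):
            geometry.cv_nearest_neighbour(np.zeros((3, 2)))


class TestExpanse:
    def test_unit_square(self):
        assert geometry.expanse(UNIT_SQUARE) == pytest.approx(np.sqrt(2) / 2)

    def test_single_fish_zero(self):
        assert geometry.expanse(np.array([[4.0, 5.0]])) == 0.0

    def test_matches_loop_oracle(self, rng):
        xy = random_frame(rng)
        c = xy.mean(axis=0)
        expected = np.mean([np.hypot(*(p - c)) for p in xy])
        assert geometry.expanse(xy) == pytest.approx(expected, rel=1e-12)


class TestConvexHullArea:
    def test_unit_square(self):
        assert geometry.convex_hull_area(UNIT_SQUARE) == pytest.approx(1.0)

    def test_collinear_zero(self):
        xy = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        assert geometry.convex_hull_area(xy) == 0.0

    def test_all_points_inside_hull(self, rng):
        from scipy.spatial import ConvexHull

        xy = random_frame(rng)
        hull = ConvexHull(xy)
        # every point lies inside (or on) all hull half-planes
        a, b = hull.equations[:, :2], hull.equations[:, 2]
        assert np.all(xy @ a.T + b <= 1e-9)
        # shoelace on the hull vertices equals the reported area
        v = xy[hull.vertices]
        x, y = v[:, 0], v[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert geometry.convex_hull_area(xy) == pytest.approx(shoelace, rel=1e-12)


class TestDistanceToWall:
    def test_tank_centre(self):
        tank = TankGeometry(45, 25, 20)
        xy = np.array([[22.5, 12.5]] * 2)
        assert geometry.distance_to_nearest_wall(xy, tank) == pytest.approx(12.5)

    def test_near_x0_wall(self):
        tank = TankGeometry(45, 25, 20)
        assert geometry.distance_to_nearest_wall(
            np.array([[1.0, 10.0]] * 2), tank
        ) == pytest.approx(1.0)

    def test_matches_four_wall_oracle(self, rng):
        tank = TankGeometry(45, 25, 20)
        for _ in range(100):
            xy = random_frame(rng)
            cx, cy = xy.mean(axis=0)
            expected = min(cx, 45 - cx, cy, 25 - cy)
            assert geometry.distance_to_nearest_wall(xy, tank) == pytest.approx(
                expected, rel=1e-12
            )

    def test_centroid_outside_raises(self):
        tank = TankGeometry(45, 25, 20)
        with pytest.raises(OutsideTankError, match="outside tank"):
            geometry.distance_to_nearest_wall(np.array([[-3.0, 5.0]] * 2), tank)


class TestComposedFrameMetrics:
    def test_unit_square_with_huge_threshold(self):
        tank = TankGeometry(45, 25, 20)
        row = geometry.compute_frame_metrics(UNIT_SQUARE, tank, threshold_cm=100.0)
        assert row["density"] == 1.0
        assert row["n_subgroups"] == 1
        assert row["largest_subgroup_size"] == 4
        assert row["convex_hull_area_cm2"] == pytest.approx(1.0)
        assert row["cv_nnd"] == pytest.approx(0.0)

    def test_fields_match_independent_calls(self):
        # coincident-ish pair + distant pair
        xy = np.array([[1.0, 1.0], [1.2, 1.0], [20.0, 20.0], [20.4, 20.0]])
        tank = TankGeometry(45, 25, 20)
        row = geometry.compute_frame_metrics(xy, tank, threshold_cm=2.0)
        assert row["mean_nnd_cm"] == pytest.approx(
            geometry.nearest_neighbour_distances(xy).mean()
        )
        assert row["cv_nnd"] == pytest.approx(geometry.cv_nearest_neighbour(xy))
        assert row["expanse_cm"] == pytest.approx(geometry.expanse(xy))
        assert row["convex_hull_area_cm2"] == pytest.approx(
            geometry.convex_hull_area(xy)
        )
        assert row["distance_to_wall_cm"] == pytest.approx(
            geometry.distance_to_nearest_wall(xy, tank)
        )
        assert row["n_subgroups"] == 2
        assert row["density"] == pytest.approx(2 / 6)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    angle=st.floats(0, 2 * np.pi),
    dx=st.floats(-5, 5),
    dy=st.floats(-5, 5),
)
def test_rigid_motion_invariance(seed, angle, dx, dy):
    """Distance-based metrics are unchanged by rotation + translation."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(5, 15, (7, 2))
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    moved = xy @ rot.T + np.array([dx, dy])
    for fn in (
        geometry.expanse,
        geometry.convex_hull_area,
        geometry.cv_nearest_neighbour,
        geometry.mean_interindividual_distance,
    ):
        assert fn(moved) == pytest.approx(fn(xy), rel=1e-8, abs=1e-10)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_mean_nnd_bounded_by_mean_iid(seed):
    """The nearest neighbour is a minimum over the same distance set."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 30, (7, 2))
    assert geometry.nearest_neighbour_distances(xy).mean() <= (
        geometry.mean_interindividual_distance(xy) + 1e-12
    )
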