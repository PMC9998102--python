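"""Convex-hull geometry against independent oracles and invariants."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phewas_volcano import HullPolygon, Point2D, category_hulls, convex_hull, expand_hull
from phewas_volcano.hulls import point_in_polygon, polygon_area

from conftest import brute_force_hull_vertices, edge_oracle_hull_vertices


def pts(*pairs):
    return [Point2D(x, y) for x, y in pairs]


def as_tuples(vertices):
    return {(v.x, v.y) for v in vertices}


def assert_canonical(vertices):
    """Counter-clockwise, starting at the lexicographic minimum, strictly convex."""
    assert list(vertices)[0] == min(vertices)
    assert polygon_area(vertices) > 0
    n = len(vertices)
    for i in range(n):
        o, a, b = vertices[i], vertices[(i + 1) % n], vertices[(i + 2) % n]
        cross = (a.x - o.x) * (b.y - o.y) - (a.y - o.y) * (b.x - o.x)
        assert cross > 0, "three consecutive vertices are collinear or clockwise"


class TestConvexHull:
    def test_triangle(self):
        tri = pts((0, 0), (2, 0), (1, 2))
        hull = convex_hull(tri)
        assert as_tuples(hull) == {(0, 0), (2, 0), (1, 2)}
        assert_canonical(hull)

    def test_interior_point_excluded(self):
        square = pts((0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5))
        hull = convex_hull(square)
        assert as_tuples(hull) == {(0, 0), (1, 0), (1, 1), (0, 1)}

    def test_collinear_boundary_point_dropped(self):
        hull = convex_hull(pts((0, 0), (1, 0), (2, 0), (1, 1)))
        assert as_tuples(hull) == {(0, 0), (2, 0), (1, 1)}

    @pytest.mark.parametrize(
        "degenerate",
        [[], [(0, 0)], [(0, 0), (1, 1)], [(0, 0), (1, 1), (2, 2), (3, 3)],
         [(0, 0), (0, 0), (1, 1)]],
    )
    def test_degenerate_inputs_give_none(self, degenerate):
        assert convex_hull(pts(*degenerate)) is None

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            Point2D(float("nan"), 0.0)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            arr = rng.uniform(-5, 5, size=(50, 2))
            hull = convex_hull([Point2D(x, y) for x, y in arr])
            assert as_tuples(hull) == brute_force_hull_vertices(arr)
            assert_canonical(hull)

    def test_matches_edge_oracle_on_random_sets(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            arr = rng.normal(size=(40, 2))
            hull = convex_hull([Point2D(x, y) for x, y in arr])
            assert as_tuples(hull) == edge_oracle_hull_vertices(arr)

    def test_all_points_inside_or_on_hull(self):
        rng = np.random.default_rng(5)
        arr = rng.uniform(-1, 1, size=(200, 2))
        points = [Point2D(x, y) for x, y in arr]
        hull = convex_hull(points)
        for p in points:
            assert point_in_polygon(p, hull)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(
        st.tuples(st.integers(-10, 10), st.integers(-10, 10)),
        min_size=3, max_size=20))
    def test_area_invariant_under_permutation(self, coords):
        points = pts(*coords)
        hull = convex_hull(points)
        reversed_hull = convex_hull(points[::-1])
        if hull is None:
            assert reversed_hull is None
            return
        assert polygon_area(hull) == pytest.approx(polygon_area(reversed_hull))
        assert as_tuples(hull) == as_tuples(reversed_hull)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(
        st.tuples(st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False)),
        min_size=3, max_size=15),
        st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_adding_interior_point_never_changes_hull(self, coords, u, v):
        points = pts(*coords)
        hull = convex_hull(points)
        if hull is None:
            return
        # a convex combination of three hull vertices is interior-or-boundary
        a, b, c = hull[0], hull[1], hull[2]
        w0 = (1 - u) * (1 - v)
        w1 = u * (1 - v)
        w2 = v
        interior = Point2D(
            w0 * a.x + w1 * b.x + w2 * c.x,
            w0 * a.y + w1 * b.y + w2 * c.y,
        )
        again = convex_hull(points + [interior])
        assert again is not None and as_tuples(again) == as_tuples(hull)

    def test_exhaustive_small_grid(self):
        """Exact agreement with the convex-combination oracle for every
        subset of the 3x3 integer grid (includes all collinear/degenerate
        configurations)."""
        grid = list(itertools.product(range(3), repeat=2))
        for k in range(3, 10):
            for subset in itertools.combinations(grid, k):
                hull = convex_hull(pts(*subset))
                oracle = brute_force_hull_vertices(subset)
                if len(oracle) < 3:
                    assert hull is None
                else:
                    assert hull is not None and as_tuples(hull) == oracle


class TestCategoryHulls:
    def test_two_categories(self):
        points = [(Point2D(float(x), float(y)), "A") for x, y in
                  [(0, 0), (2, 0), (1, 2), (1, 1), (0.5, 0.3)]]
        points += [(Point2D(float(x) + 10, float(y)), "B") for x, y in
                   [(0, 0), (2, 0), (1, 2), (1, 1), (0.2, 0.8)]]
        hulls = category_hulls(points)
        assert [h.category for h in hulls] == ["A", "B"]

    def test_small_category_skipped(self):
        points = [(Point2D(0, 0), "A"), (Point2D(1, 1), "A"),
                  (Point2D(0, 0), "B"), (Point2D(1, 0), "B"), (Point2D(0, 1), "B")]
        hulls = category_hulls(points)
        assert [h.category for h in hulls] == ["B"]

    def test_collinear_category_skipped(self):
        points = [(Point2D(float(i), float(i)), "diag") for i in range(5)]
        assert category_hulls(points) == []

    def test_min_points_threshold(self):
        points = [(Point2D(float(x), float(y)), "A") for x, y in
                  [(0, 0), (1, 0), (0, 1), (1, 1)]]
        assert len(category_hulls(points, min_points=3)) == 1
        assert category_hulls(points, min_points=5) == []
        with pytest.raises(ValueError):
            category_hulls(points, min_points=2)

    def test_hull_may_cross_zero_effect_line(self):
        """Categories mixing risk and protective effects hull across beta=0
        (e.g. T2D risk / hyperlipidemia protection at the same variant)."""
        points = [(Point2D(x, y), "endocrine") for x, y in
                  [(-0.32, 10.1), (0.15, 9.0), (0.2, 12.0), (-0.1, 8.0)]]
        (hull,) = category_hulls(points)
        xs = [v.x for v in hull.vertices]
        assert min(xs) < 0 < max(xs)


class TestExpandHull:
    def triangle(self):
        return HullPolygon("c", (Point2D(0, 0), Point2D(2, 0), Point2D(1, 2)))

    def test_zero_padding_identity(self):
        h = self.triangle()
        assert expand_hull(h, 0.0) is h

    def test_original_vertices_strictly_inside(self):
        h = self.triangle()
        big = expand_hull(h, 0.1)
        for v in h.vertices:
            assert point_in_polygon(v, big.vertices, eps=-1e-9)

    def test_negative_padding_rejected(self):
        with pytest.raises(ValueError):
            expand_hull(self.triangle(), -0.5)

    def test_vertices_move_exactly_padding(self):
        h = self.triangle()
        big = expand_hull(h, 0.25)
        for a, b in zip(h.vertices, big.vertices):
            assert math.hypot(b.x - a.x, b.y - a.y) == pytest.approx(0.25)

    def test_containment_of_all_inputs_random(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            arr = rng.uniform(-3, 3, size=(30, 2))
            points = [Point2D(x, y) for x, y in arr]
            hull = HullPolygon("c", convex_hull(points))
            big = expand_hull(hull, float(rng.uniform(0.01, 1.0)))
            for p in points:
                assert point_in_polygon(p, big.vertices)
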