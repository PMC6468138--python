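"""RMT projection, convex hulls, polygon areas and breadth ratios."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull as ScipyHull

from macroniche import (
    MacronutrientProfile,
    NicheHull,
    RMTPoint,
    ValidationError,
    breadth_ratio,
    convex_hull,
    food_hull,
    hull_area,
    to_rmt,
)
from macroniche.rmt import shoelace_area
from macroniche.synthetic import gen_food_profiles

AXIS_PAIRS = (("C", "P"), ("C", "L"), ("P", "L"))


class TestToRmt:
    def test_projects_chosen_components(self):
        p = MacronutrientProfile(41.0, 7.5, 51.5)
        pt = to_rmt(p, ("C", "P"))
        assert (pt.x, pt.y) == (51.5, 41.0)
        assert pt.implicit == pytest.approx(7.5)

    def test_simplex_vertex(self):
        pt = to_rmt(MacronutrientProfile(0.0, 0.0, 100.0), ("C", "P"))
        assert (pt.x, pt.y) == (100.0, 0.0)

    def test_duplicate_axes_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            to_rmt(MacronutrientProfile(30, 30, 40), ("P", "P"))

    def test_full_names_accepted(self):
        p = MacronutrientProfile(20.0, 30.0, 50.0)
        assert to_rmt(p, ("carbohydrate", "protein")).as_tuple() == (50.0, 20.0)


class TestConvexHull:
    def test_square_excludes_center(self):
        pts = [RMTPoint(*c) for c in [(0, 0), (10, 0), (10, 10), (0, 10), (5, 5)]]
        hull = convex_hull(pts)
        assert len(hull.vertices) == 4
        assert (5.0, 5.0) not in {v.as_tuple() for v in hull.vertices}
        assert hull.n_points == 5

    def test_triangle_keeps_all_three(self):
        hull = convex_hull([RMTPoint(0, 0), RMTPoint(4, 0), RMTPoint(0, 3)])
        assert len(hull.vertices) == 3
        assert hull.area == pytest.approx(6.0)

    def test_deterministic_order_ccw_from_lexicographic_min(self):
        pts = [RMTPoint(*c) for c in [(10, 0), (0, 10), (0, 0), (10, 10)]]
        hull = convex_hull(pts)
        assert hull.vertices[0].as_tuple() == (0.0, 0.0)
        verts = [v.as_tuple() for v in hull.vertices]
        signed = sum(
            verts[i][0] * verts[(i + 1) % 4][1] - verts[(i + 1) % 4][0] * verts[i][1]
            for i in range(4)
        )
        assert signed > 0  # counter-clockwise

    def test_degenerate_inputs(self):
        two = convex_hull([RMTPoint(0, 0), RMTPoint(5, 5)])
        assert two.degenerate and two.area == 0.0
        collinear = convex_hull([RMTPoint(i, i) for i in range(5)])
        assert collinear.degenerate and collinear.area == 0.0

    def test_collinear_edge_points_excluded(self):
        pts = [RMTPoint(*c) for c in [(0, 0), (5, 0), (10, 0), (0, 10)]]
        assert len(convex_hull(pts).vertices) == 3

    def test_matches_scipy_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            coords = rng.uniform(0, 50, size=(50, 2))
            pts = [RMTPoint(x, y) for x, y in coords]
            ours = {v.as_tuple() for v in convex_hull(pts).vertices}
            ref = {tuple(coords[i]) for i in ScipyHull(coords).vertices}
            assert ours == ref
            assert convex_hull(pts).area == pytest.approx(
                ScipyHull(coords).volume
            )

    def test_matches_brute_force_extremality_oracle(self):
        # p is a hull vertex iff no triangle of other points contains it
        def in_triangle(p, a, b, c):
            def cross(o, u, v):
                return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])
            d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
            return not (
                (d1 < -1e-12 or d2 < -1e-12 or d3 < -1e-12)
                and (d1 > 1e-12 or d2 > 1e-12 or d3 > 1e-12)
            )

        rng = np.random.default_rng(11)
        for _ in range(20):
            coords = [tuple(c) for c in rng.uniform(0, 40, size=(12, 2))]
            extreme = set()
            for p in coords:
                others = [q for q in coords if q != p]
                if not any(
                    in_triangle(p, a, b, c)
                    for a, b, c in itertools.combinations(others, 3)
                ):
                    extreme.add(p)
            ours = {v.as_tuple() for v in convex_hull(RMTPoint(*c) for c in coords).vertices}
            assert ours == extreme

    def test_hull_is_idempotent_and_ignores_interior_points(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 50, size=(30, 2))
        hull = convex_hull([RMTPoint(x, y) for x, y in coords])
        again = convex_hull(hull.vertices)
        assert [v.as_tuple() for v in again.vertices] == [
            v.as_tuple() for v in hull.vertices
        ]
        centroid = np.mean([v.as_tuple() for v in hull.vertices], axis=0)
        bigger = convex_hull(
            [RMTPoint(x, y) for x, y in coords] + [RMTPoint(*centroid)]
        )
        assert bigger.area == pytest.approx(hull.area)
        assert len(bigger.vertices) == len(hull.vertices)


class TestArea:
    def test_right_triangle_and_unit_square(self):
        tri = convex_hull([RMTPoint(0, 0), RMTPoint(4, 0), RMTPoint(0, 3)])
        assert hull_area(tri) == pytest.approx(6.0)
        sq = convex_hull(
            [RMTPoint(0, 0), RMTPoint(1, 0), RMTPoint(1, 1), RMTPoint(0, 1)]
        )
        assert hull_area(sq) == pytest.approx(1.0)

    def test_shoelace_matches_fan_triangulation(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            coords = rng.uniform(0, 50, size=(20, 2))
            hull = convex_hull([RMTPoint(x, y) for x, y in coords])
            verts = [v.as_tuple() for v in hull.vertices]
            fan = sum(
                abs(
                    (verts[i][0] - verts[0][0]) * (verts[i + 1][1] - verts[0][1])
                    - (verts[i][1] - verts[0][1]) * (verts[i + 1][0] - verts[0][0])
                )
                / 2.0
                for i in range(1, len(verts) - 1)
            )
            assert hull.area == pytest.approx(fan, abs=1e-9)

    def test_area_invariant_under_rigid_motions(self):
        rng = np.random.default_rng(21)
        coords = rng.uniform(0, 10, size=(15, 2))
        hull = [
            np.array(v.as_tuple())
            for v in convex_hull([RMTPoint(x, y) for x, y in coords]).vertices
        ]
        base = shoelace_area([tuple(v) for v in hull])
        for _ in range(10):
            theta = rng.uniform(0, 2 * math.pi)
            rot = np.array(
                [[math.cos(theta), -math.sin(theta)],
                 [math.sin(theta), math.cos(theta)]]
            )
            shift = rng.uniform(-100, 100, size=2)
            moved = [tuple(rot @ v + shift) for v in hull]
            assert shoelace_area(moved) == pytest.approx(base, rel=1e-9)


class TestAxisInvariance:
    def test_hull_area_is_axis_pair_invariant(self):
        # profile points lie on the plane P+L+C=100; every coordinate
        # projection scales in-plane areas identically
        for seed in range(10):
            profiles = gen_food_profiles(10, seed=seed)
            areas = [food_hull(profiles, axes=ax).area for ax in AXIS_PAIRS]
            assert max(areas) - min(areas) < 1e-8 * max(areas[0], 1.0)

    def test_breadth_ratio_is_axis_pair_invariant(self, diets, profiles):
        for ax in AXIS_PAIRS:
            hulls = {
                name: food_hull(
                    [profiles[name][f] for f in d.items], label=name, axes=ax
                )
                for name, d in diets.items()
            }
            ratio, larger = breadth_ratio(hulls["dhr_summer"], hulls["ksl_summer"])
            assert ratio == pytest.approx(3.13, abs=0.01)
            assert larger == "dhr_summer"


class TestBreadthRatio:
    def test_identical_hulls_ratio_one(self):
        h = convex_hull([RMTPoint(0, 0), RMTPoint(4, 0), RMTPoint(0, 3)], "a")
        assert breadth_ratio(h, h) == (1.0, "a")

    def test_zero_area_hull_rejected(self):
        h = convex_hull([RMTPoint(0, 0), RMTPoint(4, 0), RMTPoint(0, 3)], "a")
        flat = convex_hull([RMTPoint(0, 0), RMTPoint(1, 1)], "b")
        with pytest.raises(ValidationError):
            breadth_ratio(h, flat)

    def test_orders_larger_first(self):
        big = convex_hull([RMTPoint(0, 0), RMTPoint(10, 0), RMTPoint(0, 10)], "big")
        small = convex_hull([RMTPoint(0, 0), RMTPoint(2, 0), RMTPoint(0, 2)], "small")
        assert breadth_ratio(small, big) == (pytest.approx(25.0), "big")
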