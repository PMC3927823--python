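"""Convex-hull ranges, projection and overlap proportions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import MultiPoint, Point, Polygon

from specmode import geo
from specmode.geo import (
    ConvexRange,
    InputFormatError,
    PointLocality,
    ProjectedPoint,
    ValidationError,
    build_hull,
    intersection_area,
    overlap_matrix,
    overlap_proportion,
    project,
    read_localities,
)

from conftest import pp, write_locality_csv


def square_range(x0, y0, side, species="sp"):
    pts = [pp(x0, y0), pp(x0 + side, y0), pp(x0 + side, y0 + side), pp(x0, y0 + side)]
    return build_hull(pts, species)


def mc_area(points_xy, hull_vertices, n_samples, rng):
    """Monte-Carlo membership estimate of the hull polygon's area."""
    poly = Polygon(hull_vertices)
    minx, miny, maxx, maxy = poly.bounds
    xs = rng.uniform(minx, maxx, n_samples)
    ys = rng.uniform(miny, maxy, n_samples)
    from shapely import contains_xy

    inside = contains_xy(poly, xs, ys)
    box_area = (maxx - minx) * (maxy - miny)
    p = inside.mean()
    est = p * box_area
    se = box_area * math.sqrt(p * (1 - p) / n_samples)
    return est, se


# ---------------------------------------------------------------------------
# localities


class TestReadLocalities:
    def test_wellformed_rows_read_identically(self, tmp_path):
        f = write_locality_csv(
            tmp_path / "loc.csv",
            ["sp1,29.1,-29.5", "sp1,29.2,-29.6", "sp2,30.0,-30.0"],
        )
        locs = read_localities(f)
        assert len(locs) == 3
        assert locs[0] == PointLocality("sp1", 29.1, -29.5)

    def test_out_of_range_latitude_names_row(self, tmp_path):
        f = write_locality_csv(tmp_path / "loc.csv", ["sp1,29.1,-29.5", "sp1,29.2,95"])
        with pytest.raises(ValidationError, match="row 3"):
            read_localities(f)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert read_localities(f) == []

    def test_missing_column_is_format_error(self, tmp_path):
        f = write_locality_csv(tmp_path / "loc.csv", ["sp1,29.1"], header="species,longitude")
        with pytest.raises(InputFormatError, match="latitude"):
            read_localities(f)

    def test_optional_precision_and_source_carried(self, tmp_path):
        f = write_locality_csv(
            tmp_path / "loc.csv",
            ["sp1,29.1,-29.5,7500,herbarium"],
            header="species,longitude,latitude,precision_m,source",
        )
        (loc,) = read_localities(f)
        assert loc.precision_radius_m == 7500.0
        assert loc.source == "herbarium"


class TestProject:
    def test_one_degree_longitude_at_equator(self):
        locs = [PointLocality("s", 0.0, 0.0), PointLocality("s", 1.0, 0.0)]
        a, b = project(locs, reference_latitude=0.0)
        # R * pi / 180 km per degree at the equator
        assert abs(b.x - a.x) == pytest.approx(6371 * math.pi / 180, abs=1e-6)
        assert abs(b.x - a.x) == pytest.approx(111.19, abs=0.01)

    def test_reference_origin_maps_to_zero(self):
        (p,) = project([PointLocality("s", 29.0, -29.0)])
        assert (p.x, p.y) == (0.0, 0.0)

    def test_longitude_shift_leaves_pairwise_distances(self, rng):
        lons = rng.uniform(28, 30, 10)
        lats = rng.uniform(-30, -28, 10)
        locs = [PointLocality("s", lo, la) for lo, la in zip(lons, lats)]
        shifted = [PointLocality("s", lo + 5.0, la) for lo, la in zip(lons, lats)]
        p1 = project(locs)
        p2 = project(shifted)
        d1 = [math.hypot(a.x - b.x, a.y - b.y) for a in p1 for b in p1]
        d2 = [math.hypot(a.x - b.x, a.y - b.y) for a in p2 for b in p2]
        assert np.allclose(d1, d2)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            project([])


# ---------------------------------------------------------------------------
# hulls


class TestBuildHull:
    def test_square_with_interior_point(self, unit_square_points):
        r = build_hull(unit_square_points + [pp(0.5, 0.5)], "sq")
        assert not r.degenerate
        assert len(r.vertices) == 4
        assert r.area == pytest.approx(1.0)
        assert r.n_localities == 5

    def test_collinear_points_degenerate(self):
        r = build_hull([pp(0, 0), pp(1, 1), pp(2, 2)], "line")
        assert r.degenerate
        assert r.area == 0.0

    def test_single_point_degenerate(self):
        r = build_hull([pp(3, 4)], "pt")
        assert r.degenerate and r.n_localities == 1

    def test_vertices_counter_clockwise(self, rng):
        pts = [pp(x, y) for x, y in rng.normal(0, 10, (30, 2))]
        r = build_hull(pts, "s")
        v = [(p.x, p.y) for p in r.vertices]
        area2 = sum(
            v[i][0] * v[(i + 1) % len(v)][1] - v[(i + 1) % len(v)][0] * v[i][1]
            for i in range(len(v))
        )
        assert area2 > 0  # CCW orientation has positive signed area

    def test_hull_area_matches_monte_carlo(self, rng):
        angles = rng.uniform(0, 2 * math.pi, 200)
        radii = np.sqrt(rng.uniform(0, 1, 200))
        pts = [pp(r * math.cos(a), r * math.sin(a)) for r, a in zip(radii, angles)]
        hull = build_hull(pts, "disc")
        est, se = mc_area(pts, [(p.x, p.y) for p in hull.vertices], 10**6, rng)
        assert abs(hull.area - est) <= max(3 * se, 0.01 * hull.area)

    def test_hull_matches_shapely(self, rng):
        pts = rng.normal(0, 5, (50, 2))
        hull = build_hull([pp(x, y) for x, y in pts], "s")
        shapely_hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        assert hull.area == pytest.approx(shapely_hull.area, rel=1e-12)
        ours = Polygon([(p.x, p.y) for p in hull.vertices])
        assert ours.symmetric_difference(shapely_hull).area < 1e-9

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=3,
            max_size=25,
        )
    )
    def test_every_point_inside_or_on_hull(self, coords):
        hull = build_hull([pp(x, y) for x, y in coords], "s")
        if hull.degenerate:
            return
        poly = Polygon([(p.x, p.y) for p in hull.vertices]).buffer(1e-9)
        assert all(poly.covers(Point(x, y)) for x, y in coords)

    def test_adding_interior_points_keeps_hull(self, rng):
        outer = rng.normal(0, 10, (20, 2))
        hull1 = build_hull([pp(x, y) for x, y in outer], "s")
        centroid = outer.mean(axis=0)
        interior = centroid + 0.01 * rng.normal(0, 1, (10, 2))
        hull2 = build_hull(
            [pp(x, y) for x, y in np.vstack([outer, interior])], "s"
        )
        assert [(p.x, p.y) for p in hull1.vertices] == [
            (p.x, p.y) for p in hull2.vertices
        ]


# ---------------------------------------------------------------------------
# intersection and overlap


class TestIntersectionArea:
    def test_identical_unit_squares(self):
        a = square_range(0, 0, 1, "a")
        b = square_range(0, 0, 1, "b")
        assert intersection_area(a, b) == pytest.approx(1.0)

    def test_half_offset_squares(self):
        a = square_range(0, 0, 1, "a")
        b = square_range(0.5, 0, 1, "b")
        assert intersection_area(a, b) == pytest.approx(0.5)

    def test_degenerate_input_errors(self):
        a = square_range(0, 0, 1, "a")
        d = build_hull([pp(0, 0)], "d")
        with pytest.raises(ValueError, match="degenerate"):
            intersection_area(a, d)

    def test_random_convex_pair_matches_monte_carlo(self, rng):
        penta = build_hull(
            [pp(x, y) for x, y in rng.normal(0, 3, (12, 2))], "p"
        )
        tri = build_hull([pp(x, y) for x, y in rng.normal(1, 2, (3, 2))], "t")
        if tri.degenerate:
            pytest.skip("random triangle degenerate")
        inter = Polygon([(p.x, p.y) for p in penta.vertices]).intersection(
            Polygon([(p.x, p.y) for p in tri.vertices])
        )
        got = intersection_area(penta, tri)
        if inter.is_empty:
            assert got == 0.0
            return
        minx, miny, maxx, maxy = inter.bounds
        n = 10**6
        xs = rng.uniform(minx, maxx, n)
        ys = rng.uniform(miny, maxy, n)
        from shapely import contains_xy

        p_in = contains_xy(inter, xs, ys).mean()
        box = (maxx - minx) * (maxy - miny)
        se = box * math.sqrt(p_in * (1 - p_in) / n)
        assert abs(got - p_in * box) <= max(3 * se, 0.01 * got)


class TestOverlapProportion:
    def test_embedded_square_scores_one(self):
        big = square_range(0, 0, 10, "big")
        small = square_range(4, 4, 1, "small")
        assert overlap_proportion(big, small) == 1.0

    def test_disjoint_scores_zero(self):
        a = square_range(0, 0, 1, "a")
        b = square_range(5, 5, 1, "b")
        assert overlap_proportion(a, b) == 0.0

    def test_half_offset_scores_half(self):
        a = square_range(0, 0, 1, "a")
        b = square_range(0.5, 0, 1, "b")
        assert overlap_proportion(a, b) == pytest.approx(0.5)

    def test_symmetric(self, rng):
        for _ in range(20):
            a = build_hull([pp(x, y) for x, y in rng.normal(0, 2, (8, 2))], "a")
            b = build_hull([pp(x, y) for x, y in rng.normal(1, 2, (8, 2))], "b")
            assert overlap_proportion(a, b) == overlap_proportion(b, a)

    def test_degenerate_point_inside_polygon(self):
        sq = square_range(0, 0, 2, "sq")
        point = build_hull([pp(1, 1)], "pt")
        assert overlap_proportion(point, sq) == 1.0
        outside = build_hull([pp(5, 5)], "out")
        assert overlap_proportion(outside, sq) == 0.0

    def test_degenerate_fraction_of_localities(self):
        sq = square_range(0, 0, 2, "sq")
        seg = build_hull([pp(1, 1), pp(1, 5), pp(1, 9)], "seg")
        assert seg.degenerate
        assert overlap_proportion(seg, sq) == pytest.approx(1 / 3)

    def test_degenerate_pair_coincidence(self):
        a = build_hull([pp(0, 0)], "a")
        b = build_hull([pp(0, 0)], "b")
        c = build_hull([pp(1, 0)], "c")
        assert overlap_proportion(a, b) == 1.0
        assert overlap_proportion(a, c) == 0.0

    def test_scaling_invariance(self, rng):
        pts_a = rng.normal(0, 2, (10, 2))
        pts_b = rng.normal(1, 2, (10, 2))
        for c in (0.1, 7.0):
            a1 = build_hull([pp(x, y) for x, y in pts_a], "a")
            b1 = build_hull([pp(x, y) for x, y in pts_b], "b")
            a2 = build_hull([pp(c * x, c * y) for x, y in pts_a], "a")
            b2 = build_hull([pp(c * x, c * y) for x, y in pts_b], "b")
            assert a2.area == pytest.approx(c**2 * a1.area, rel=1e-9)
            assert overlap_proportion(a2, b2) == pytest.approx(
                overlap_proportion(a1, b1), rel=1e-9
            )


class TestOverlapMatrix:
    def test_disjoint_ranges_zero_offdiagonal(self):
        ranges = [square_range(10 * i, 0, 1, f"s{i}") for i in range(3)]
        M = overlap_matrix(ranges)
        assert np.allclose(M.values, np.eye(3))

    def test_duplicate_geometry_scores_one(self):
        ranges = [square_range(0, 0, 1, "a"), square_range(0, 0, 1, "b")]
        M = overlap_matrix(ranges)
        assert M.get("a", "b") == 1.0

    def test_duplicate_id_errors(self):
        ranges = [square_range(0, 0, 1, "a"), square_range(2, 0, 1, "a")]
        with pytest.raises(ValueError, match="duplicate"):
            overlap_matrix(ranges)

    def test_matches_pairwise_recomputation(self, rng):
        ranges = [
            build_hull(
                [pp(x, y) for x, y in rng.normal(rng.uniform(-3, 3), 2, (12, 2))],
                f"s{i}",
            )
            for i in range(10)
        ]
        M = overlap_matrix(ranges)
        assert np.allclose(M.values, M.values.T)
        assert np.all((M.values >= 0) & (M.values <= 1))
        assert np.allclose(np.diag(M.values), 1.0)
        for i in range(10):
            for j in range(10):
                if i != j:
                    assert M.values[i, j] == overlap_proportion(ranges[i], ranges[j])

    def test_csv_roundtrip(self, tmp_path, rng):
        ranges = [square_range(0, 0, 1, "a"), square_range(0.25, 0, 1, "b")]
        M = overlap_matrix(ranges)
        f = tmp_path / "m.csv"
        M.to_csv(f)
        M2 = geo.OverlapMatrix.from_csv(f)
        assert M2.species_ids == M.species_ids
        assert np.allclose(M2.values, M.values)
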