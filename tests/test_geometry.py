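"""Geometry primitives against brute-force oracles and exact constructions."""

import numpy as np
import pytest

from limbalign import geometry as geo
from limbalign.geometry import GeometryError, Line, Outline, Point


def _square_mask(size=10, lo=3, hi=7):
    m = np.zeros((size, size), dtype=bool)
    m[lo:hi, lo:hi] = True
    return m


def _random_blob(rng, size=40):
    m = np.zeros((size, size), dtype=bool)
    cy, cx = rng.integers(12, size - 12, 2)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(4):
        dy, dx = rng.integers(-6, 7, 2)
        r = rng.integers(4, 9)
        m |= (yy - cy - dy) ** 2 + (xx - cx - dx) ** 2 <= r**2
    return m


class TestExtractOutline:
    def test_square_boundary_loop(self):
        out = geo.extract_outline(_square_mask())
        # a 4x4 filled square has a 12-pixel boundary loop
        assert len(out) == 12
        assert out.x.min() == 3 and out.x.max() == 6
        assert out.y.min() == 3 and out.y.max() == 6

    def test_largest_component_wins(self):
        m = np.zeros((30, 30), dtype=bool)
        m[2:12, 2:7]  = True  # 50 px
        m[20:25, 20:21] = True  # 5 px
        out = geo.extract_outline(m)
        assert out.x.max() <= 6 and out.y.max() <= 11

    def test_empty_mask_rejected(self):
        with pytest.raises(GeometryError, match="empty-mask"):
            geo.extract_outline(np.zeros((5, 5), dtype=bool))

    def test_outline_encloses_component(self, rng):
        """Rasterising the traced polygon recovers the component (flood-fill
        oracle)."""
        from matplotlib.path import Path as MplPath

        for _ in range(5):
            m = _random_blob(rng)
            comp = geo.largest_component(m)
            out = geo.extract_outline(m)
            path = MplPath(out.points)
            yy, xx = np.nonzero(comp)
            inside = path.contains_points(np.c_[xx, yy], radius=0.5)
            assert inside.all()

    def test_translation_equivariance(self, rng):
        m = _random_blob(rng)
        out = geo.extract_outline(m)
        shifted = np.zeros((m.shape[0] + 5, m.shape[1] + 3), dtype=bool)
        shifted[5:, 3:] = m
        out2 = geo.extract_outline(shifted)
        assert np.allclose(out2.points, out.points + [3, 5])


class TestFitCircle:
    @pytest.mark.parametrize("cx,cy,r", [(50, 60, 20), (0, 0, 1), (-5, 120, 300)])
    def test_exact_on_noiseless_circle(self, cx, cy, r):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.c_[cx + r * np.cos(t), cy + r * np.sin(t)]
        c = geo.fit_circle(pts)
        assert abs(c.center.x - cx) < 1e-6 * max(1, r)
        assert abs(c.center.y - cy) < 1e-6 * max(1, r)
        assert abs(c.radius - r) < 1e-6 * r

    def test_exact_on_quarter_arc(self):
        t = np.linspace(0, np.pi / 2, 60)
        pts = np.c_[10 + 7 * np.cos(t), -3 + 7 * np.sin(t)]
        c = geo.fit_circle(pts)
        assert abs(c.center.x - 10) < 1e-9 and abs(c.center.y + 3) < 1e-9

    def test_circumcircle_of_three_points(self):
        c = geo.fit_circle([(0.0, 0.0), (2.0, 0.0), (1.0, 1.0)])
        assert c.center.x == pytest.approx(1.0, abs=1e-9)
        assert c.center.y == pytest.approx(0.0, abs=1e-9)
        assert c.radius == pytest.approx(1.0, abs=1e-9)

    def test_noisy_circle_against_grid_search(self, rng):
        """Kasa fit vs a dense grid-search minimiser of the geometric
        residual, on jittered circle points."""
        t = rng.uniform(0, 2 * np.pi, 100)
        pts = np.c_[50 + 20 * np.cos(t), 60 + 20 * np.sin(t)]
        pts += rng.normal(0, 0.5, pts.shape)
        c = geo.fit_circle(pts)

        def geom_rss(cx, cy):
            d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
            return ((d - d.mean()) ** 2).sum()

        grid = np.linspace(-1.0, 1.0, 41)
        best = min(
            ((geom_rss(50 + dx, 60 + dy), 50 + dx, 60 + dy) for dx in grid for dy in grid),
        )
        assert np.hypot(c.center.x - best[1], c.center.y - best[2]) < 0.2
        assert np.hypot(c.center.x - 50, c.center.y - 60) < 0.2

    def test_collinear_points_rejected(self):
        with pytest.raises(GeometryError, match="degenerate-circle"):
            geo.fit_circle([(0, 0), (1, 1), (2, 2), (3, 3)])


class TestConvexHull:
    def test_square_with_interior_points(self, rng):
        corners = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        inner = rng.uniform(0.1, 0.9, size=(20, 2))
        hull = geo.convex_hull(np.vstack([corners, inner]))
        assert len(hull) == 4
        assert {tuple(p) for p in hull} == {tuple(p) for p in corners}

    def test_triangle(self):
        pts = np.array([(0, 0), (4, 1), (2, 5)], dtype=float)
        hull = geo.convex_hull(pts)
        assert {tuple(p) for p in hull} == {tuple(p) for p in pts}

    def test_matches_halfplane_oracle(self, rng):
        """Hull vertices = points not strictly inside any triangle of other
        points (brute-force O(n^3) half-plane test)."""
        for _ in range(100):
            pts = rng.uniform(0, 10, size=(12, 2))
            hull = {tuple(p) for p in geo.convex_hull(pts)}

            def on_hull(p):
                # p is a hull vertex iff it lies inside no triangle of
                # other points
                from itertools import combinations

                def cross2(u, v):
                    return u[0] * v[1] - u[1] * v[0]

                others = [q for q in pts if not np.array_equal(q, p)]
                for a, b, c in combinations(others, 3):
                    d1 = cross2(b - a, p - a)
                    d2 = cross2(c - b, p - b)
                    d3 = cross2(a - c, p - c)
                    if (d1 >= 0 and d2 >= 0 and d3 >= 0) or (
                        d1 <= 0 and d2 <= 0 and d3 <= 0
                    ):
                        return False
                return True

            expected = {tuple(p) for p in pts if on_hull(p)}
            assert hull == expected

    def test_collinear_rejected(self):
        with pytest.raises(GeometryError, match="degenerate-hull"):
            geo.convex_hull([(i, 2.0 * i) for i in range(5)])


class TestBoundingBox:
    def test_square_outline(self):
        m = np.zeros((12, 12), dtype=bool)
        m[3:10, 2:8] = True
        box = geo.bounding_box(geo.extract_outline(m))
        assert (box.xmin, box.ymin, box.xmax, box.ymax) == (2, 3, 7, 9)

    def test_degenerate_outline_rejected(self):
        m = np.zeros((5, 10), dtype=bool)
        m[2, 1:8] = True  # single row: no valid closed outline
        with pytest.raises(GeometryError):
            geo.extract_outline(m)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            out = geo.extract_outline(_random_blob(rng))
            box = geo.bounding_box(out)
            assert box.xmin == min(p[0] for p in out.points)
            assert box.xmax == max(p[0] for p in out.points)
            assert box.ymin == min(p[1] for p in out.points)
            assert box.ymax == max(p[1] for p in out.points)


def _comb_mask(tips=((10, 5), (30, 7)), base_y=20, width=40, tooth_hw=4):
    m = np.zeros((30, width + 10), dtype=bool)
    m[base_y : base_y + 6, 2 : width + 8] = True
    for tx, ty in tips:
        for y in range(ty, base_y):
            hw = max(1, int(tooth_hw * (y - ty + 1) / (base_y - ty)))
            m[y, tx - hw : tx + hw + 1] = True
        m[ty, tx] = True
    return m


class TestFindTwoPeaks:
    def test_two_tooth_comb(self):
        out = geo.extract_outline(_comb_mask())
        i1, i2 = geo.find_two_peaks(out)
        assert (out.x[i1], out.y[i1]) == (10, 5)
        assert (out.x[i2], out.y[i2]) == (30, 7)

    def test_single_bump_rejected(self):
        m = np.zeros((20, 20), dtype=bool)
        yy, xx = np.mgrid[0:20, 0:20]
        m[(yy - 14) ** 2 + (xx - 10) ** 2 <= 36] = True
        with pytest.raises(GeometryError, match="peaks-not-found"):
            geo.find_two_peaks(geo.extract_outline(m))


class TestDirectedAngle:
    def test_quarter_turn_sign_convention(self):
        a = Line(Point(0, 0), Point(1, 0))   # +x
        b = Line(Point(0, 0), Point(0, 1))   # +y (down in image coords)
        assert geo.directed_angle(a, b) == pytest.approx(90.0)

    def test_identity_is_zero(self):
        a = Line(Point(3, 4), Point(7, -2))
        assert geo.directed_angle(a, a) == 0.0

    def test_antisymmetry_and_additivity(self, rng):
        for _ in range(300):
            dirs = rng.normal(size=(3, 2))
            lines = [Line(Point(0, 0), Point(*d)) for d in dirs]
            a, b, c = lines
            assert geo.directed_angle(a, b) == pytest.approx(
                -geo.directed_angle(b, a), abs=1e-9
            )
            total = (
                geo.directed_angle(a, b)
                + geo.directed_angle(b, c)
                - geo.directed_angle(a, c)
            )
            assert min(abs(total), abs(abs(total) - 360)) < 1e-9

    def test_matches_atan2_oracle(self, rng):
        for _ in range(200):
            p = rng.normal(size=(2, 2, 2)) * 10
            a = Line(Point(*p[0, 0]), Point(*p[0, 1]))
            b = Line(Point(*p[1, 0]), Point(*p[1, 1]))
            va = np.array([a.q.x - a.p.x, a.q.y - a.p.y])
            vb = np.array([b.q.x - b.p.x, b.q.y - b.p.y])
            expected = np.degrees(
                np.arctan2(vb[1], vb[0]) - np.arctan2(va[1], va[0])
            )
            expected = (expected + 180) % 360 - 180
            if expected == -180:
                expected = 180
            assert geo.directed_angle(a, b) == pytest.approx(expected, abs=1e-9)

    def test_scale_and_translation_invariance(self, rng):
        p = rng.normal(size=(2, 2, 2)) * 5
        a = Line(Point(*p[0, 0]), Point(*p[0, 1]))
        b = Line(Point(*p[1, 0]), Point(*p[1, 1]))
        ref = geo.directed_angle(a, b)
        for s, (dx, dy) in [(3.0, (10, -4)), (0.25, (-7, 2))]:
            a2 = Line(
                Point(s * a.p.x + dx, s * a.p.y + dy),
                Point(s * a.q.x + dx, s * a.q.y + dy),
            )
            b2 = Line(
                Point(s * b.p.x + dx, s * b.p.y + dy),
                Point(s * b.q.x + dx, s * b.q.y + dy),
            )
            assert geo.directed_angle(a2, b2) == pytest.approx(ref, abs=1e-9)


class TestClosestPointOnOutline:
    def test_tangent_circle(self):
        m = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[0:40, 0:40]
        m[(yy - 20) ** 2 + (xx - 20) ** 2 <= 100] = True
        out = geo.extract_outline(m)
        tangent = Line(Point(0, 30), Point(40, 30))  # horizontal tangent below
        p = geo.closest_point_on_outline(out, tangent)
        assert abs(p.x - 20) <= 1 and abs(p.y - 30) <= 1

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            out = geo.extract_outline(_random_blob(rng))
            q = rng.normal(size=(2, 2)) * 20
            line = Line(Point(*q[0]), Point(*q[0] + q[1] + 0.1))
            p = geo.closest_point_on_outline(out, line)
            d = [abs(line.signed_distance(out.point(i))) for i in range(len(out))]
            assert abs(line.signed_distance(p)) == pytest.approx(min(d), abs=1e-12)

    def test_empty_region_rejected(self, rng):
        out = geo.extract_outline(_random_blob(rng))
        with pytest.raises(GeometryError, match="empty-region"):
            geo.closest_point_on_outline(
                out, Line(Point(0, 0), Point(1, 0)), region=np.array([], dtype=int)
            )
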