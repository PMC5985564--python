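import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oleomap import geometry as geo
from oleomap.errors import ConsistencyError, DomainError, GeometryError
from oleomap.synthetic import SyntheticSliceSpec, generate_contour

from conftest import circle_polygon


def star_polygon(seed, n_vertices=720):
    """Seeded star-shaped polygon with radii in roughly 80–120 px."""
    rng = np.random.default_rng(seed)
    amps = rng.uniform(0.01, 0.08, size=4)
    spec = SyntheticSliceSpec(
        size=256, mean_radius=100.0, amplitudes=tuple(amps), seed=seed,
        n_contour_points=n_vertices,
    )
    return generate_contour(spec, np.random.default_rng(seed)), spec.center


def nearest_vertex_radius(poly, center, phi):
    """Dense-resampling oracle: radius of the vertex nearest in angle."""
    rel = poly - np.asarray(center)
    ang = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * math.pi)
    rad = np.hypot(rel[:, 0], rel[:, 1])
    d = np.abs(ang - phi % (2 * math.pi))
    d = np.minimum(d, 2 * math.pi - d)
    return rad[np.argmin(d)]


class TestPointOps:
    @pytest.mark.parametrize(
        "pt,c,expected",
        [((10, 5), (3, 2), (7, 3)), ((4, -1), (4, -1), (0, 0)), ((0, 0), (4, -1), (-4, 1))],
    )
    def test_recenter(self, pt, c, expected):
        assert geo.recenter(pt, c) == expected

    @pytest.mark.parametrize("xy,r", [((3, 4), 5), ((0, 0), 0), ((-5, 12), 13)])
    def test_radius(self, xy, r):
        assert geo.radius(*xy) == pytest.approx(r)

    @pytest.mark.parametrize(
        "xy,phi",
        [((1, 0), 0.0), ((0, 1), math.pi / 2), ((0, -1), 3 * math.pi / 2),
         ((-1, 0), math.pi), ((1, -1e-12), None)],
    )
    def test_polar_angle(self, xy, phi):
        got = geo.polar_angle(*xy)
        assert 0 <= got < 2 * math.pi
        if phi is not None:
            assert got == pytest.approx(phi)

    def test_polar_angle_zero_vector(self):
        with pytest.raises(GeometryError):
            geo.polar_angle(0.0, 0.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        x=st.floats(-1e3, 1e3, allow_nan=False),
        y=st.floats(-1e3, 1e3, allow_nan=False),
    )
    def test_polar_angle_matches_atan2(self, x, y):
        if x == 0 and y == 0:
            return
        expected = math.atan2(y, x) % (2 * math.pi)
        diff = abs(geo.polar_angle(x, y) - expected) % (2 * math.pi)
        assert min(diff, 2 * math.pi - diff) < 1e-9


class TestEdgeRadius:
    def test_circle(self):
        g = geo.SliceGeometry(center=(128, 128), edge=circle_polygon((128, 128), 100))
        for phi in np.linspace(0, 2 * math.pi, 17, endpoint=False):
            assert geo.edge_radius_at_angle(g, float(phi)) == pytest.approx(100, abs=0.5)

    def test_square(self):
        sq = np.array([[50, -50], [50, 50], [-50, 50], [-50, -50]], float)
        # densify square edges so the >=16-vertex invariant holds
        pts = []
        for a, b in zip(sq, np.roll(sq, -1, axis=0)):
            pts.append(np.linspace(a, b, 25, endpoint=False))
        poly = np.concatenate(pts) + 100
        g = geo.SliceGeometry(center=(100, 100), edge=poly)
        assert geo.edge_radius_at_angle(g, 0.0) == pytest.approx(50, abs=1e-6)
        assert geo.edge_radius_at_angle(g, math.pi / 4) == pytest.approx(
            50 * math.sqrt(2), abs=1e-6
        )

    def test_star_polygons_match_dense_oracle(self):
        for seed in range(10):
            poly, center = star_polygon(seed)
            g = geo.SliceGeometry(center=center, edge=poly)
            # half-spacing offset keeps queries off the vertex grid
            phis = np.linspace(0, 2 * math.pi, 360, endpoint=False) + math.pi / 720
            got = geo.edge_radius_at_angle(g, phis)
            oracle = np.array([nearest_vertex_radius(poly, center, p) for p in phis])
            assert np.max(np.abs(got - oracle)) <= 1.5

    def test_cove_takes_farthest_intersection(self):
        # non-star-shaped contour: a vertical channel cut into the disk makes
        # the +x ray cross the boundary three times (50, 70, 100); the
        # farthest crossing defines r_CE, so a droplet between channel and
        # rim keeps pp < 100
        from shapely.geometry import Point, box

        disk = Point(200, 200).buffer(100, quad_segs=180)
        cove = disk.difference(box(250, 190, 270, 320))
        poly = np.asarray(cove.exterior.coords)[:-1]
        g = geo.SliceGeometry(center=(200, 200), edge=poly)
        assert geo.edge_radius_at_angle(g, 0.0) == pytest.approx(100, abs=1.0)
        (rec,) = geo.map_droplets(np.array([[285.0, 200.0]]), g)
        assert rec.pp == pytest.approx(85, abs=1.5)
        assert rec.pp < 100

    def test_center_outside_polygon_rejected(self):
        with pytest.raises(GeometryError):
            geo.SliceGeometry(center=(500, 500), edge=circle_polygon((128, 128), 100))


class TestRelativeDistance:
    def test_basic_values(self):
        assert geo.relative_distance(50, 100) == 50.0
        assert geo.relative_distance(100, 100) == 100.0
        assert geo.relative_distance(0, 100) == 0.0

    def test_halo_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert geo.relative_distance(103, 100) == 100.0

    def test_far_outside_is_error(self):
        with pytest.raises(ConsistencyError):
            geo.relative_distance(110, 100)

    def test_zero_edge_radius(self):
        with pytest.raises(GeometryError):
            geo.relative_distance(10, 0)


class TestAssignClass:
    @pytest.mark.parametrize("pp,cls", [(0, 1), (100, 9), (50, 5), (11.0, 1), (99.99, 9)])
    def test_examples(self, pp, cls):
        assert geo.assign_class(pp) == cls

    def test_boundaries_half_open(self):
        for k in range(1, 9):
            edge = 100.0 * k / 9.0
            assert geo.assign_class(np.nextafter(edge, 0)) == k
            assert geo.assign_class(edge) == k + 1

    @pytest.mark.parametrize("pp", [-0.01, 100.01])
    def test_domain(self, pp):
        with pytest.raises(DomainError):
            geo.assign_class(pp)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(pp=st.floats(0, 100, allow_nan=False))
    def test_class_consistent_with_boundaries(self, pp):
        cls = geo.assign_class(pp)
        bounds = geo.ClassBinning().boundaries
        assert bounds[cls - 1] <= pp and (pp < bounds[cls] or pp == 100.0)


class TestRelativeDistanceMap:
    def test_disk_class_area_fractions(self):
        g = geo.SliceGeometry(
            center=(320, 320), edge=circle_polygon((320, 320), 300, n=1440), scale=2.0
        )
        _, counts, areas = geo.relative_distance_map(g, (640, 640))
        frac = counts / counts.sum()
        expected = np.array([(k**2 - (k - 1) ** 2) / 81 for k in range(1, 10)])
        assert np.max(np.abs(frac - expected)) <= 0.01
        np.testing.assert_allclose(areas, counts * (2.0 / 1000.0) ** 2)

    def test_partition_property(self):
        poly, center = star_polygon(3)
        g = geo.SliceGeometry(center=center, edge=poly)
        pp_map, counts, _ = geo.relative_distance_map(g, (256, 256))
        assert counts.sum() == np.sum(~np.isnan(pp_map))

    def test_rotation_invariance_of_areas(self):
        poly, center = star_polygon(4)
        g0 = geo.SliceGeometry(center=center, edge=poly)
        _, c0, _ = geo.relative_distance_map(g0, (256, 256))
        # rotate polygon+center by 90° about the image center of a 256 frame
        cx = (256 - 1) / 2
        rot = np.stack(
            [cx - (poly[:, 1] - cx), cx + (poly[:, 0] - cx)], axis=1
        )
        rcenter = (cx - (center[1] - cx), cx + (center[0] - cx))
        g1 = geo.SliceGeometry(center=rcenter, edge=rot)
        _, c1, _ = geo.relative_distance_map(g1, (256, 256))
        assert np.all(np.abs(c0 - c1) / c0.sum() <= 0.01)


class TestInvariances:
    def droplets_and_geometry(self, seed=5, n=60):
        poly, center = star_polygon(seed)
        rng = np.random.default_rng(seed)
        g = geo.SliceGeometry(center=center, edge=poly)
        phis = rng.uniform(0, 2 * math.pi, n)
        fr = rng.uniform(0.05, 0.98, n)
        r_ce = geo.edge_radius_at_angle(g, phis)
        pts = np.stack(
            [center[0] + fr * r_ce * np.cos(phis), center[1] + fr * r_ce * np.sin(phis)],
            axis=1,
        )
        return pts, poly, center

    def pps(self, pts, poly, center):
        g = geo.SliceGeometry(center=center, edge=poly)
        return np.array([r.pp for r in geo.map_droplets(pts, g)])

    def test_translation_invariance(self):
        pts, poly, center = self.droplets_and_geometry()
        shift = np.array([37.5, -12.25])
        pp0 = self.pps(pts, poly, center)
        pp1 = self.pps(pts + shift, poly + shift, tuple(np.asarray(center) + shift))
        np.testing.assert_allclose(pp0, pp1, atol=1e-9)

    def test_rotation_invariance(self):
        pts, poly, center = self.droplets_and_geometry()
        c = np.asarray(center)
        rot = lambda p: np.stack(
            [c[0] - (p[:, 1] - c[1]), c[1] + (p[:, 0] - c[0])], axis=1
        )
        pp0 = self.pps(pts, poly, center)
        pp1 = self.pps(rot(pts), rot(poly), center)
        assert np.max(np.abs(pp0 - pp1)) <= 1.0

    def test_scaling_invariance(self):
        pts, poly, center = self.droplets_and_geometry()
        c = np.asarray(center)
        s = 2.75
        pp0 = self.pps(pts, poly, center)
        pp1 = self.pps(c + s * (pts - c), c + s * (poly - c), center)
        np.testing.assert_allclose(pp0, pp1, atol=1e-6)

    def test_class_count_conservation(self):
        pts, poly, center = self.droplets_and_geometry(seed=9, n=80)
        g = geo.SliceGeometry(center=center, edge=poly)
        recs = geo.map_droplets(pts, g)
        counts = np.bincount([r.class_index for r in recs], minlength=10)[1:]
        assert counts.sum() == len(pts)

    def test_circle_closed_form(self):
        center = (128.0, 128.0)
        g = geo.SliceGeometry(center=center, edge=circle_polygon(center, 100, n=1440))
        rng = np.random.default_rng(2)
        phis = rng.uniform(0, 2 * math.pi, 40)
        fr = rng.uniform(0.1, 0.95, 40)
        pts = np.stack(
            [center[0] + fr * 100 * np.cos(phis), center[1] + fr * 100 * np.sin(phis)],
            axis=1,
        )
        pps = self.pps(pts, circle_polygon(center, 100, n=1440), center)
        np.testing.assert_allclose(pps, 100 * fr, atol=0.2)
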