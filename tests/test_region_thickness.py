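import math

import numpy as np
import pytest

from lc3d import region_thickness as rt
from lc3d.annotations import ReliableBound
from lc3d.phantom import oracle_avg_thickness, truth_annotations
from lc3d.surface_model import build_lc_model

from conftest import quiet_spec, truth_of


def circle_points(R, M=24, center=(0.0, 0.0)):
    th = np.arange(M) * 2 * math.pi / M
    return np.column_stack([center[0] + R * np.cos(th), center[1] + R * np.sin(th)])


class TestClosedCurve:
    def test_circle_through_24_points_stays_on_circle(self):
        R = 600.0
        curve = rt.build_closed_boundary(circle_points(R))
        u = np.linspace(0, 2 * math.pi, 3000)
        radius = np.hypot(*curve(u).T)
        assert np.abs(radius - R).max() < 1e-3 * R

    def test_square_corners_interpolated(self):
        pts = [(1, 0), (0, 1), (-1, 0), (0, -1)]
        curve = rt.build_closed_boundary(pts)
        got = curve(np.arange(4) * math.pi / 2)
        np.testing.assert_allclose(got, pts, atol=1e-12)

    def test_seam_is_closed_and_c1(self):
        curve = rt.build_closed_boundary(circle_points(500.0, M=8))
        np.testing.assert_allclose(curve(0.0), curve(2 * math.pi), atol=1e-9)
        eps = 1e-7
        np.testing.assert_allclose(
            (curve(eps) - curve(0.0)) / eps,
            (curve(2 * math.pi) - curve(2 * math.pi - eps)) / eps,
            atol=1e-3,
        )

    def test_self_intersecting_boundary_rejected(self):
        # figure-eight control points
        pts = [(0, 0), (2, 1), (0, 2), (2, -1), (0, 1), (2, 2), (1, -2), (2, 0)]
        with pytest.raises(ValueError, match="self-intersecting"):
            rt.build_closed_boundary(pts)


class TestCurveArea:
    def test_circle_area_within_half_percent(self):
        R = 564.18958  # radius whose disc is 1.000 mm^2
        area = rt.curve_area(rt.build_closed_boundary(circle_points(R)))
        assert area == pytest.approx(1.000, rel=0.005)

    def test_small_curve_area_vanishes(self):
        area = rt.curve_area(rt.build_closed_boundary(circle_points(1e-3)))
        assert area < 1e-11

    def test_area_invariant_under_rotation(self):
        pts = circle_points(400.0) * np.array([1.0, 0.6])  # ellipse
        ang = 0.7
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        a0 = rt.curve_area(rt.build_closed_boundary(pts))
        a1 = rt.curve_area(rt.build_closed_boundary(pts @ rot.T))
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_orientation_independent(self):
        pts = circle_points(300.0)
        a_ccw = rt.curve_area(rt.build_closed_boundary(pts))
        a_cw = rt.curve_area(rt.build_closed_boundary(pts[::-1]))
        assert a_cw == pytest.approx(a_ccw, rel=1e-9)


class TestMask:
    @pytest.fixture
    def model(self, flat_annotations):
        return build_lc_model(flat_annotations, N=40)

    def test_full_bounds_cover_whole_grid(self, model, flat_truth):
        R = flat_truth.bmo_radius
        bounds = [ReliableBound(i, 0.0, R) for i in range(24)]
        boundary = rt.build_closed_boundary(
            circle_points(1.01 * R, center=flat_truth.center)
        )
        mask = rt.mask_polar_grid(model, bounds, boundary)
        assert mask.mask.all()

    def test_half_radius_bounds_mask_inner_region(self, model, flat_truth):
        R = flat_truth.bmo_radius
        bounds = [ReliableBound(i, 0.0, R / 2) for i in range(24)]
        boundary = rt.build_closed_boundary(
            circle_points(1.01 * R, center=flat_truth.center)
        )
        mask = rt.mask_polar_grid(model, bounds, boundary)
        expected = model.anterior.r_grid <= R / 2 + 1e-9
        np.testing.assert_array_equal(mask.mask, expected)

    def test_boundary_alone_clips_nodes(self, model, flat_truth):
        # generous bounds but a half-radius extruded boundary
        R = flat_truth.bmo_radius
        bounds = [ReliableBound(i, 0.0, R) for i in range(24)]
        boundary = rt.build_closed_boundary(circle_points(R / 2, center=flat_truth.center))
        mask = rt.mask_polar_grid(model, bounds, boundary)
        frac = mask.mask.sum() / mask.mask.size
        # half-radius disc holds the inner half of each axis's nodes
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_excluded_axis_has_no_nodes(self, model, flat_truth):
        R = flat_truth.bmo_radius
        bounds = [ReliableBound(i, 0.0, R) for i in range(1, 24)]  # axis 0 missing
        boundary = rt.build_closed_boundary(circle_points(1.01 * R, center=flat_truth.center))
        mask = rt.mask_polar_grid(model, bounds, boundary)
        assert not mask.mask[0].any()
        assert mask.mask[1:].all()

    def test_extrapolated_nodes_excluded(self, flat_truth):
        aset = truth_annotations(flat_truth, M=24, points_per_axis=9, r_min_um=200.0)
        model = build_lc_model(aset, N=40)
        R = flat_truth.bmo_radius
        bounds = [ReliableBound(i, 0.0, R) for i in range(24)]
        boundary = rt.build_closed_boundary(circle_points(1.01 * R, center=flat_truth.center))
        mask = rt.mask_polar_grid(model, bounds, boundary)
        inner = model.anterior.r_grid < 200.0 - 1e-9
        assert not mask.mask[inner].any()
        assert mask.mask[~inner].all()


class TestThickness:
    def _map_for(self, spec, N=140):
        truth = truth_of(spec)
        aset = truth_annotations(truth, M=24, points_per_axis=9)
        model = build_lc_model(aset, N=N)
        boundary = rt.boundary_from_bounds(aset.reliable, model.bmo_center, model.delta_theta)
        mask = rt.mask_polar_grid(model, aset.reliable, boundary)
        return truth, model, boundary, rt.compute_thickness_map(model, mask)

    def test_flat_slab_thickness_constant(self):
        _, _, _, tmap = self._map_for(quiet_spec(), N=40)
        np.testing.assert_allclose(tmap.thickness[tmap.mask.mask], 250.0, atol=1e-9)

    def test_tilted_slab_thickness_sec_alpha(self):
        _, _, _, tmap = self._map_for(quiet_spec(shape="tilted", tilt_deg=5.0), N=40)
        np.testing.assert_allclose(
            tmap.thickness[tmap.mask.mask], 250.0 / math.cos(math.radians(5.0)), atol=1e-6
        )

    def test_bowl_thickness_matches_generator_within_3um(self):
        truth, model, _, tmap = self._map_for(
            quiet_spec(shape="bowl", posterior_shape="flat")
        )
        cx, cy = truth.center
        grid = model.anterior
        theta = grid.theta()[:, None]
        x = cx + grid.r_grid * np.cos(theta)
        y = cy + grid.r_grid * np.sin(theta)
        expected = truth.thickness_z(x, y)
        m = tmap.mask.mask
        assert np.abs(tmap.thickness[m] - expected[m]).max() < 3.0

    def test_average_equals_area_weighted_oracle_within_1pct(self):
        truth, _, boundary, tmap = self._map_for(
            quiet_spec(shape="bowl", posterior_shape="flat")
        )
        avg = rt.average_thickness(tmap)
        oracle = oracle_avg_thickness(truth, boundary)
        assert avg == pytest.approx(oracle, rel=0.01)

    def test_weights_reproduce_boundary_polygon_area_within_2pct(self):
        # full-grid weights vs the area of the curve through the terminals
        truth, model, _, tmap = self._map_for(quiet_spec())
        term_curve = rt.boundary_from_bounds(
            [ReliableBound(i, 0.0, model.anterior.terminal_r[i]) for i in range(24)],
            model.bmo_center, model.delta_theta,
        )
        assert tmap.area_weight.sum() == pytest.approx(term_curve.area_um2(), rel=0.02)

    def test_avg_between_min_and_max(self):
        truth, _, _, tmap = self._map_for(quiet_spec(shape="bowl", posterior_shape="flat"))
        avg = rt.average_thickness(tmap)
        m = tmap.mask.mask
        assert tmap.thickness[m].min() <= avg <= tmap.thickness[m].max()

    def test_shrinking_region_keeps_constant_thickness(self, flat_truth):
        aset = truth_annotations(flat_truth, M=24, points_per_axis=9)
        model = build_lc_model(aset, N=60)
        for frac in (0.8, 0.5, 0.3):
            R = frac * flat_truth.bmo_radius
            bounds = [ReliableBound(i, 0.0, R) for i in range(24)]
            boundary = rt.build_closed_boundary(circle_points(R, center=flat_truth.center))
            mask = rt.mask_polar_grid(model, bounds, boundary)
            tmap = rt.compute_thickness_map(model, mask)
            assert rt.average_thickness(tmap) == pytest.approx(250.0, abs=1e-9)

    def test_unweighted_mean_exposed(self):
        _, _, _, tmap = self._map_for(quiet_spec(), N=40)
        assert rt.average_thickness(tmap, weighted=False) == pytest.approx(250.0)

    def test_empty_mask_rejected(self):
        _, model, boundary, tmap = self._map_for(quiet_spec(), N=40)
        tmap.mask.mask[:] = False
        with pytest.raises(ValueError, match="empty"):
            rt.average_thickness(tmap)

    def test_two_equal_area_halves_average_to_midpoint(self):
        _, model, boundary, tmap = self._map_for(quiet_spec(), N=40)
        m = tmap.mask.mask
        half = np.zeros_like(tmap.thickness)
        half[:12] = 200.0
        half[12:] = 300.0
        tmap.thickness = half
        # equal-area half-disc split: weights are angularly uniform
        assert rt.average_thickness(tmap) == pytest.approx(250.0, abs=1e-9)


class TestAreaRatio:
    def test_table_style_division(self):
        assert rt.area_ratio(1.02, 2.32) == pytest.approx(43.97, abs=0.01)

    def test_equal_areas_100(self):
        assert rt.area_ratio(1.5, 1.5) == 100.0

    def test_zero_reliable_is_zero(self):
        assert rt.area_ratio(0.0, 2.0) == 0.0

    def test_zero_bmo_rejected(self):
        with pytest.raises(ValueError):
            rt.area_ratio(1.0, 0.0)


class TestRotationInvariance:
    def test_avglct_invariant_under_axis_rotation(self):
        from lc3d.pipeline import run_eye

        spec = quiet_spec(shape="bowl", posterior_shape="flat")
        truth = truth_of(spec)
        aset = truth_annotations(truth, M=24, points_per_axis=9)
        base = run_eye(aset, N=60).avg_lct_um

        # rotate every annotation by one axis step (relabel i -> i+1)
        from lc3d.annotations import AnnotationSet, BMOMark, BorderPolyline, ReliableBound

        rot_borders = [
            BorderPolyline((b.axis_index + 1) % 24, b.surface, b.points)
            for b in aset.borders
        ]
        rot_rel = [
            ReliableBound((r.axis_index + 1) % 24, r.r_inner, r.r_outer)
            for r in aset.reliable
        ]
        rot_edges = {(i + 1) % 24: p for i, p in aset.bmo.edge_points.items()}
        rotated = AnnotationSet(
            bmo=BMOMark(center=aset.bmo.center, edge_points=rot_edges),
            borders=rot_borders, reliable=rot_rel, delta_theta=aset.delta_theta,
        )
        assert run_eye(rotated, N=60).avg_lct_um == pytest.approx(base, abs=0.5)
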