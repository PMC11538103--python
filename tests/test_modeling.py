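import numpy as np
import pytest

from lsatrace.modeling import (BezierCenterline, VesselModel, arc_length, bland_altman,
                               compare_models, estimate_diameters, export_tube_mesh,
                               fit_centerline, morphometry)
from lsatrace.phantom import (PhantomSpec, TubeSpec, make_straight_tube_phantom,
                              render_phantom)
from lsatrace.tracking import BranchTrack


class TestBezier:
    def test_segment_endpoint_property(self, rng):
        seg = rng.uniform(0, 5, (1, 4, 3))
        c = BezierCenterline(seg)
        assert np.allclose(c.evaluate(0, 0.0)[0], seg[0, 0])
        assert np.allclose(c.evaluate(0, 1.0)[0], seg[0, 3])

    def test_fit_interpolates_every_input_point(self, rng):
        pts = np.cumsum(rng.uniform(-0.5, 1.0, (12, 3)), axis=0)
        c = fit_centerline(pts)
        knots = [c.evaluate(0, 0.0)[0]] + [c.evaluate(s, 1.0)[0] for s in range(c.n_segments)]
        keep = np.ones(len(pts), bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
        assert np.allclose(np.asarray(knots), pts[keep], atol=1e-9)

    def test_collinear_points_give_chord_length(self):
        pts = np.stack([np.linspace(0, 10, 8), np.zeros(8), np.zeros(8)], axis=1)
        c = fit_centerline(pts)
        assert arc_length(c) == pytest.approx(10.0, rel=1e-3)

    def test_circular_arc_oracle(self):
        """Points on a 90-degree arc of radius 5 mm: fitted curve within 0.05 mm."""
        th = np.linspace(0, np.pi / 2, 12)
        pts = np.stack([5 * np.cos(th), 5 * np.sin(th), np.zeros_like(th)], axis=1)
        c = fit_centerline(pts)
        dense = c.sample(64)
        dev = np.abs(np.linalg.norm(dense[:, :2], axis=1) - 5.0)
        assert dev.max() < 0.05
        assert arc_length(c) == pytest.approx(5 * np.pi / 2, rel=5e-3)

    def test_duplicate_points_collapsed_and_degenerate_rejected(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        c = fit_centerline(pts)
        assert c.n_segments == 2
        with pytest.raises(ValueError, match="distinct"):
            fit_centerline(np.zeros((3, 3)))

    def test_four_segment_circle_length(self):
        k = 0.5522847498
        P = [np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
             np.array([-1.0, 0, 0]), np.array([0, -1.0, 0])]
        T = [np.array([0, 1.0, 0]), np.array([-1.0, 0, 0]),
             np.array([0, -1.0, 0]), np.array([1.0, 0, 0])]
        segs = [[P[i], P[i] + k * T[i], P[(i + 1) % 4] - k * T[(i + 1) % 4], P[(i + 1) % 4]]
                for i in range(4)]
        c = BezierCenterline(np.asarray(segs, dtype=float))
        assert abs(arc_length(c) - 2 * np.pi) / (2 * np.pi) < 0.005

    def test_refinement_invariance_of_length(self, rng):
        pts = np.cumsum(rng.uniform(-0.3, 1.0, (9, 3)), axis=0)
        c = fit_centerline(pts)
        l1 = np.linalg.norm(np.diff(c.sample(64), axis=0), axis=1).sum()
        l2 = np.linalg.norm(np.diff(c.sample(128), axis=0), axis=1).sum()
        assert abs(l2 - l1) / l1 < 1e-3


class TestDiameters:
    @pytest.mark.parametrize("radius", [0.2, 0.3, 0.45, 0.6])
    def test_recovery_within_one_voxel(self, radius):
        spec = make_straight_tube_phantom(radius=radius, spacing=0.1, shape=(50, 50, 50))
        _vol, gt = render_phantom(spec)
        c = fit_centerline(gt.centerlines[0][::5])
        d, _pts, _flags = estimate_diameters(c, gt.mask, (0.1,) * 3)
        assert np.abs(d - 2 * radius).max() <= 0.1

    def test_single_voxel_line_measures_one_voxel(self):
        mask = np.zeros((30, 30, 30), np.uint8)
        mask[15, 15, 5:25] = 1
        c = fit_centerline(np.array([[1.5, 1.5, 0.5], [1.5, 1.5, 2.4]]))
        d, _pts, _flags = estimate_diameters(c, mask, (0.1,) * 3)
        assert np.median(d) == pytest.approx(0.113, abs=0.04)

    def test_tapering_tube_profile_decreases(self):
        tube = TubeSpec(np.array([[2.5, 2.5, 0.4], [2.5, 2.5, 4.5]]), np.array([0.6, 0.3]))
        spec = PhantomSpec(grid_shape=(50, 50, 50), spacing=(0.1,) * 3, tubes=[tube])
        _vol, gt = render_phantom(spec)
        c = fit_centerline(gt.centerlines[0][::5])
        d, _pts, _flags = estimate_diameters(c, gt.mask, (0.1,) * 3)
        # monotone decreasing after filtering, up to half-voxel jitter
        assert d[0] > d[-1]
        assert np.all(np.diff(d) <= 0.051)

    def test_out_of_mask_samples_flagged_and_filled(self):
        mask = np.zeros((40, 40, 40), np.uint8)
        mask[18:23, 18:23, 5:20] = 1
        c = fit_centerline(np.array([[2.0, 2.0, 0.6], [2.0, 2.0, 3.5]]))  # runs past mask
        d, _pts, flags = estimate_diameters(c, mask, (0.1,) * 3)
        assert flags.any()
        assert np.isfinite(d).all()


def _straight_model(length=20.0, diameter=0.6, n=15, shift=None, order=1):
    pts = np.stack([np.linspace(0, length, n), np.zeros(n), np.zeros(n)], axis=1)
    if shift is not None:
        pts = pts + shift
    tr = BranchTrack(points=pts, radii=np.full(n, diameter / 2), order=order)
    return VesselModel.from_tracks([tr])


class TestMorphometry:
    def test_straight_branch_row(self):
        t = morphometry(_straight_model())
        row = t.per_branch.iloc[0]
        assert row["order"] == 1
        assert row["length_mm"] == pytest.approx(20.0, abs=0.02)
        assert row["mean_diameter_mm"] == pytest.approx(0.6, abs=0.1)
        assert row["mean_curvature_per_mm"] < 1e-3

    def test_y_topology_counts(self):
        p1 = np.stack([np.linspace(0, 3, 8), np.zeros(8), np.zeros(8)], axis=1)
        p2 = np.stack([np.full(8, 3.0), np.linspace(0, 2, 8), np.zeros(8)], axis=1)
        p3 = np.stack([np.full(8, 3.0), np.zeros(8), np.linspace(0, 2, 8)], axis=1)
        tracks = [BranchTrack(points=p1, radii=np.full(8, 0.3), order=1),
                  BranchTrack(points=p2, radii=np.full(8, 0.2), order=2, parent=(0, 7)),
                  BranchTrack(points=p3, radii=np.full(8, 0.2), order=2, parent=(0, 7))]
        t = morphometry(VesselModel.from_tracks(tracks))
        assert t.branch_counts == {1: 1, 2: 2}

    def test_orders_above_three_capped(self):
        m = _straight_model(order=5)
        t = morphometry(m)
        assert t.per_branch.iloc[0]["order"] == 3


class TestCompareModels:
    def test_model_vs_itself_is_zero(self):
        m = _straight_model()
        c = compare_models(m, m)
        assert np.allclose(c.keypoint_offsets, 0)
        assert np.allclose(c.length_diffs, 0)
        assert np.allclose(c.diameter_diffs, 0)

    def test_translated_copy_reports_the_shift(self):
        a = _straight_model()
        b = _straight_model(shift=np.array([0.0, 0.05, 0.0]))
        c = compare_models(a, b)
        assert np.median(c.keypoint_offsets) == pytest.approx(0.05, abs=1e-6)
        assert c.length_diffs[0] == pytest.approx(0.0, abs=1e-6)

    def test_bland_altman_matches_hand_computation(self):
        x = np.array([10.0, 11.0, 12.5, 9.0, 10.5])
        y = np.array([10.2, 10.8, 12.0, 9.5, 10.0])
        mean, lo, hi = bland_altman(x, y)
        d = x - y
        sd = d.std(ddof=1)
        assert mean == pytest.approx(d.mean())
        assert lo == pytest.approx(d.mean() - 1.96 * sd)
        assert hi == pytest.approx(d.mean() + 1.96 * sd)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_models(VesselModel(), _straight_model())


class TestTubeMesh:
    def test_vertex_distance_to_axis_is_half_diameter(self):
        m = _straight_model(length=5.0, diameter=0.6)
        mesh = export_tube_mesh(m, n_theta=12)
        v = mesh.vertices
        body = v[np.abs(np.linalg.norm(v[:, 1:], axis=1) - 0.3) < 1e-6]
        assert len(body) >= 12 * 5  # all ring vertices sit at radius d/2

    def test_vertex_count_scales_with_resolution(self):
        m = _straight_model(length=5.0)
        m8 = export_tube_mesh(m, n_theta=8)
        m16 = export_tube_mesh(m, n_theta=16)
        # rings double; the two cap centers stay
        assert (len(m16.vertices) - 2) == 2 * (len(m8.vertices) - 2)

    def test_mesh_is_watertight_and_carries_diameter(self):
        m = _straight_model(length=4.0)
        mesh = export_tube_mesh(m, n_theta=10)
        assert mesh.is_watertight
        assert len(mesh.vertex_attributes["diameter"]) == len(mesh.vertices)
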