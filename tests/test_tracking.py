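import numpy as np
import pytest
from scipy.spatial import cKDTree

from lsatrace.phantom import (PhantomSpec, TubeSpec, make_large_vessel_phantom,
                              make_straight_tube_phantom, make_tree_phantom,
                              make_y_phantom, render_phantom)
from lsatrace.tracking import (Cylinder, StepForestConfig, TrackingConfig,
                               compute_step_features, detect_bifurcation, detect_seeds,
                               make_step_training_data, step, trace_tree,
                               train_step_forest)
from lsatrace.volume import Volume


class TestCylinder:
    def test_axis_normalized_and_invariants(self):
        c = Cylinder(np.zeros(3), np.array([0.0, 0.0, 2.0]), 0.3, 0.5)
        assert np.allclose(np.linalg.norm(c.axis), 1.0)
        assert np.allclose(c.end, [0, 0, 0.5])
        with pytest.raises(ValueError):
            Cylinder(np.zeros(3), np.array([0.0, 0.0, 1.0]), -0.1, 0.5)


class TestStepFeatures:
    def test_f1_is_one_inside_solid_vessel(self, straight_tube):
        _spec, vol, gt = straight_tube
        cyl = Cylinder(np.array([2.45, 2.45, 2.0]), np.array([0, 0, 1.0]), 0.15, 0.3)
        f = compute_step_features(cyl, cyl.axis, gt.mask, vol)
        assert f.f1 == 1.0

    def test_f1_f4_match_brute_force_enumeration(self, straight_tube, rng):
        """f1 and f4 agree exactly with an independent voxel-by-voxel count."""
        _spec, vol, gt = straight_tube
        sp = np.asarray(vol.spacing)
        for _ in range(10):
            base = rng.uniform(1.0, 3.5, 3)
            ax = rng.normal(0, 1, 3)
            ax /= np.linalg.norm(ax)
            cyl = Cylinder(base, ax, rng.uniform(0.1, 0.4), 0.3)
            f = compute_step_features(cyl, ax, gt.mask, vol)
            # brute force f1: loop all voxels in an enclosing box
            lo = np.floor((np.minimum(base, cyl.end) - cyl.radius - 0.1) / sp).astype(int)
            hi = np.ceil((np.maximum(base, cyl.end) + cyl.radius + 0.1) / sp).astype(int)
            n_in = n_vessel = 0
            for i in range(max(lo[0], 0), min(hi[0] + 1, 50)):
                for j in range(max(lo[1], 0), min(hi[1] + 1, 50)):
                    for k in range(max(lo[2], 0), min(hi[2] + 1, 50)):
                        x = np.array([i, j, k]) * sp - base
                        a = x @ cyl.axis
                        if 0 <= a <= cyl.height and np.linalg.norm(x - a * cyl.axis) <= cyl.radius:
                            n_in += 1
                            n_vessel += int(gt.mask[i, j, k])
            if n_in:
                assert f.f1 == pytest.approx(n_vessel / n_in)
            # brute force f4 around the end voxel
            c = np.rint(cyl.end / sp).astype(int)
            cnt = 0
            for i in range(max(c[0] - 2, 0), min(c[0] + 3, 50)):
                for j in range(max(c[1] - 2, 0), min(c[1] + 3, 50)):
                    for k in range(max(c[2] - 2, 0), min(c[2] + 3, 50)):
                        cnt += int(gt.mask[i, j, k])
            assert f.f4 == cnt

    def test_f3_angle_limits(self, straight_tube):
        _spec, vol, gt = straight_tube
        z = np.array([0.0, 0.0, 1.0])
        cyl = Cylinder(np.array([2.45, 2.45, 2.0]), z, 0.2, 0.3)
        assert compute_step_features(cyl, z, gt.mask, vol).f3 == pytest.approx(0.0)
        assert compute_step_features(cyl, -z, gt.mask, vol).f3 == pytest.approx(np.pi)

    def test_f2_small_for_centered_circular_section(self, straight_tube):
        _spec, vol, gt = straight_tube
        cyl = Cylinder(np.array([2.45, 2.45, 2.0]), np.array([0, 0, 1.0]), 0.3, 0.3)
        f = compute_step_features(cyl, cyl.axis, gt.mask, vol)
        assert f.f2 <= 0.01  # one voxel^2 at 0.1 mm spacing

    def test_f5_sorted_ascending(self, straight_tube):
        _spec, vol, gt = straight_tube
        cyl = Cylinder(np.array([2.45, 2.45, 2.0]), np.array([0, 0, 1.0]), 0.2, 0.3)
        f = compute_step_features(cyl, cyl.axis, gt.mask, vol)
        assert np.all(np.diff(f.f5) >= 0)
        # a bright tube: two strongly negative and one near-zero eigenvalue
        assert f.f5[0] < 0 and abs(f.f5[2]) < abs(f.f5[0])

    def test_cylinder_outside_grid_raises(self, straight_tube):
        _spec, vol, gt = straight_tube
        cyl = Cylinder(np.array([50.0, 50.0, 50.0]), np.array([0, 0, 1.0]), 0.2, 0.3)
        with pytest.raises(ValueError, match="intersect"):
            compute_step_features(cyl, cyl.axis, gt.mask, vol)


class TestSeeds:
    def test_single_tube_one_seed_with_aligned_direction(self, straight_tube):
        _spec, vol, gt = straight_tube
        seeds = detect_seeds(gt.mask, spacing=vol.spacing)
        assert len(seeds) == 1
        assert abs(seeds[0].direction[2]) > np.cos(np.deg2rad(30))

    def test_two_disjoint_tubes_two_seeds(self):
        t1 = TubeSpec(np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 3.5]]), np.array([0.25, 0.25]))
        t2 = TubeSpec(np.array([[3.0, 3.0, 0.5], [3.0, 3.0, 3.5]]), np.array([0.25, 0.25]))
        vol, gt = render_phantom(PhantomSpec(grid_shape=(45, 45, 45), spacing=(0.1,) * 3,
                                             tubes=[t1, t2]))
        assert len(detect_seeds(gt.mask, spacing=vol.spacing)) == 2

    def test_empty_mask_gives_no_seeds(self):
        assert detect_seeds(np.zeros((10, 10, 10), np.uint8)) == []

    def test_large_vessel_junction_seed_points_away(self):
        spec = make_large_vessel_phantom()
        vol, gt = render_phantom(spec)
        seeds = detect_seeds(gt.mask, gt.large_vessel_mask, spacing=vol.spacing)
        assert len(seeds) == 1
        tube = spec.tubes[0]
        axis = tube.control_points[1] - tube.control_points[0]
        axis = axis / np.linalg.norm(axis)
        assert seeds[0].direction @ axis > np.cos(np.deg2rad(30))


class TestStepForest:
    def test_config_tree_count_honored_and_seeded(self, rng):
        X = rng.normal(0, 1, (60, 7))
        y = (X[:, 0] > 0).astype(int)
        f1 = train_step_forest((X, y), StepForestConfig(n_trees=50, seed=4))
        f2 = train_step_forest((X, y), StepForestConfig(n_trees=50, seed=4))
        assert f1.n_trees == 50
        assert np.array_equal(f1.predict_proba(X), f2.predict_proba(X))

    def test_phantom_step_labels_learnable(self, straight_forest):
        """Valid on-axis steps vs off-vessel steps: out-of-bag accuracy >= 0.9."""
        assert straight_forest.oob_accuracy is not None
        assert straight_forest.oob_accuracy >= 0.9

    def test_accepts_feature_objects(self, straight_tube):
        _spec, vol, gt = straight_tube
        cyl = Cylinder(np.array([2.45, 2.45, 2.0]), np.array([0, 0, 1.0]), 0.2, 0.3)
        good = compute_step_features(cyl, cyl.axis, gt.mask, vol)
        off = Cylinder(np.array([0.5, 0.5, 0.5]), np.array([1.0, 0, 0]), 0.2, 0.3)
        bad = compute_step_features(off, off.axis, gt.mask, vol)
        forest = train_step_forest([(good, True), (bad, False)] * 10,
                                   StepForestConfig(n_trees=10, seed=0))
        assert forest.predict_proba(good.vector())[0] > forest.predict_proba(bad.vector())[0]

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (10, 7))
        with pytest.raises(ValueError, match="both"):
            train_step_forest((X, np.ones(10)), StepForestConfig(n_trees=5))


class TestStep:
    def test_steps_advance_monotonically_along_tube(self, straight_tube, straight_forest):
        _spec, vol, gt = straight_tube
        axis = np.array([0.0, 0.0, 1.0])
        cur = Cylinder(np.array([2.45, 2.45, 0.5]), axis, 0.28, 1e-6)
        zs = [cur.end[2]]
        prev = axis
        cfg = TrackingConfig()
        for _ in range(8):
            nxt = step(cur, prev, gt.mask, vol, straight_forest, cfg)
            assert nxt is not None
            zs.append(nxt.end[2])
            assert np.arccos(np.clip(nxt.axis @ prev, -1, 1)) <= np.deg2rad(cfg.max_turn_deg) + 1e-9
            cur, prev = nxt, nxt.axis
        assert np.all(np.diff(zs) > 0)

    def test_empty_mask_stops_immediately(self, straight_tube, straight_forest):
        _spec, vol, _gt = straight_tube
        empty = np.zeros(vol.shape, np.uint8)
        cur = Cylinder(np.array([2.45, 2.45, 2.0]), np.array([0, 0, 1.0]), 0.2, 1e-6)
        assert step(cur, cur.axis, empty, vol, straight_forest) is None


class TestBifurcation:
    def test_mid_tube_yields_single_continuation(self, straight_tube):
        _spec, _vol, gt = straight_tube
        mid = gt.centerlines[0][len(gt.centerlines[0]) // 2]
        kids = detect_bifurcation(mid, 0.3, gt.mask, (0.1,) * 3,
                                  incoming_axis=np.array([0.0, 0, 1]))
        assert len(kids) == 1
        assert kids[0] @ np.array([0, 0, 1.0]) > 0.9

    def test_tube_endpoint_is_terminal(self, straight_tube):
        _spec, _vol, gt = straight_tube
        end = gt.centerlines[0][-1]
        kids = detect_bifurcation(end, 0.3, gt.mask, (0.1,) * 3,
                                  incoming_axis=np.array([0.0, 0, 1]))
        assert len(kids) == 0

    def test_y_junction_yields_two_children(self, y_phantom):
        _spec, _vol, gt = y_phantom
        j = gt.bifurcation_points[0]
        kids = detect_bifurcation(j, 0.3, gt.mask, (0.1,) * 3,
                                  incoming_axis=np.array([0.0, 0, 1]))
        assert len(kids) == 2


class TestTraceTree:
    def test_single_tube_single_order1_branch(self, straight_tube, straight_forest):
        _spec, vol, gt = straight_tube
        tracks = trace_tree(detect_seeds(gt.mask, spacing=vol.spacing),
                            gt.mask, vol, straight_forest)
        assert len(tracks) == 1
        assert tracks[0].order == 1

    def test_traced_length_and_offset_on_straight_tube(self, straight_tube, straight_forest):
        _spec, vol, gt = straight_tube
        tracks = trace_tree(detect_seeds(gt.mask, spacing=vol.spacing),
                            gt.mask, vol, straight_forest)
        gt_len = np.linalg.norm(gt.centerlines[0][-1] - gt.centerlines[0][0])
        assert abs(tracks[0].length - gt_len) / gt_len < 0.10
        d, _ = cKDTree(gt.centerlines[0]).query(tracks[0].points)
        assert d.mean() < 0.1          # < 1 voxel

    def test_y_phantom_one_primary_two_secondary(self, y_phantom, y_forest):
        _spec, vol, gt = y_phantom
        tracks = trace_tree(detect_seeds(gt.mask, spacing=vol.spacing),
                            gt.mask, vol, y_forest)
        assert sorted(t.order for t in tracks) == [1, 2, 2]
        kids = [t for t in tracks if t.parent is not None]
        off = min(np.linalg.norm(k.points[0] - gt.bifurcation_points[0]) for k in kids)
        assert off < 0.2               # within 2 voxels

    def test_two_level_tree_reaches_third_order(self):
        vol, gt = render_phantom(make_tree_phantom(seed=1, n_levels=2, shape=(80, 80, 80)))
        X, y = make_step_training_data(vol, gt, 300, 300, seed=0)
        forest = train_step_forest((X, y), StepForestConfig(n_trees=100, seed=0))
        tracks = trace_tree(detect_seeds(gt.mask, spacing=vol.spacing), gt.mask, vol, forest)
        orders = [t.order for t in tracks]
        assert orders.count(1) >= 1
        assert orders.count(2) >= 2
        assert orders.count(3) >= 2

    def test_terminates_on_arbitrary_mask(self, rng, straight_forest):
        blob = (rng.uniform(size=(20, 20, 20)) < 0.3).astype(np.uint8)
        vol = Volume(blob * 100.0, (0.1,) * 3, intensity_scale="standardized")
        seeds = detect_seeds(blob, spacing=vol.spacing)
        tracks = trace_tree(seeds, blob, vol, straight_forest,
                            TrackingConfig(max_steps=50, max_branches=20))
        assert len(tracks) <= 20
        for t in tracks:
            assert len(t.points) >= 2
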