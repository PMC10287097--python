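"""Robust IRLS-ICP registration: criteria, pre-processing, solve, tracking."""

from dataclasses import replace

import numpy as np
import pytest

from headmotion.geometry import RigidTransform, compose, hpd, invert
from headmotion.registration import (AnchorPoint, PointCloud, RobustConfig,
                                     TrackingLossError, criterion_value,
                                     grid_undersample, irls_weight, register,
                                     remove_distant_outliers, robust_bound,
                                     track_sequence)
from headmotion.synthetic import (ScenarioConfig, make_truth_trace,
                                  render_frames)
from conftest import random_transform

I = RigidTransform.identity()


class TestCriterion:
    @pytest.mark.parametrize("res,bound,expected", [
        (1.0, 2.0, 0.5),    # quadratic branch: ½·1²
        (2.0, 2.0, 2.0),    # continuity at the bound: ½·2² = 2·2 − 2
        (4.0, 2.0, 6.0),    # linear branch: 2·4 − 2²/2
    ])
    def test_huber_values(self, res, bound, expected):
        assert criterion_value(res, bound, "huber") == pytest.approx(expected)

    def test_huber_continuity_and_differentiability_at_bound(self):
        Z, eps = 2.0, 1e-7
        lo = criterion_value(Z - eps, Z, "huber")
        hi = criterion_value(Z + eps, Z, "huber")
        assert hi - lo == pytest.approx(2 * eps * Z, rel=1e-3)

    def test_identity_is_plain_least_squares(self):
        r = np.array([0.0, 1.0, 10.0])
        np.testing.assert_allclose(criterion_value(r, 2.0, "identity"),
                                   0.5 * r ** 2)

    @pytest.mark.parametrize("kind", ["huber", "tukey", "cauchy", "welsch"])
    def test_criteria_agree_with_least_squares_near_zero(self, kind):
        # all criteria are ½res² to leading order
        assert criterion_value(1e-4, 2.0, kind) == pytest.approx(
            0.5e-8, rel=1e-3)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            criterion_value(1.0, 2.0, "l1")
        with pytest.raises(ValueError):
            RobustConfig(criterion="l1")


class TestIRLSWeight:
    def test_huber_examples(self):
        assert irls_weight(1.0, 2.0, "huber") == 1.0
        assert irls_weight(4.0, 2.0, "huber") == 0.5

    def test_redescending_criteria_vanish_for_gross_outliers(self):
        assert irls_weight(1e3, 2.0, "tukey") == 0.0
        assert irls_weight(1e3, 2.0, "welsch") == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("kind", ["huber", "tukey", "cauchy", "welsch",
                                      "identity"])
    def test_monotone_nonincreasing_and_normalized(self, kind):
        r = np.linspace(0, 20, 400)
        w = irls_weight(r, 2.0, kind)
        assert w[0] == pytest.approx(1.0)
        assert np.all(np.diff(w) <= 1e-12)
        assert np.all((w >= 0) & (w <= 1))


class TestRobustBound:
    def test_examples(self):
        assert robust_bound([1, 2, 3], 0.2) == pytest.approx(2.4)
        assert robust_bound([5.0], 0.0) == 5.0
        assert robust_bound([0.0, 0.0, 0.0], 0.2) == 0.0

    def test_even_count_uses_midpoint(self):
        assert robust_bound([1.0, 2.0, 4.0, 10.0], 0.0) == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            robust_bound([], 0.2)


class TestPreprocessing:
    def test_aligned_cloud_fully_kept(self, reference):
        kept = remove_distant_outliers(reference, reference, 5.0, I)
        assert len(kept) == len(reference)

    def test_displaced_points_removed_exactly(self, reference, rng):
        pts = reference.points.copy()
        displaced = rng.choice(len(pts), len(pts) // 10, replace=False)
        pts[displaced] += [0.0, 0.0, 100.0]  # clear of the whole face surface
        cloud = PointCloud(pts, grid_index=reference.grid_index)
        kept = remove_distant_outliers(cloud, reference, 5.0, I)
        assert len(kept) == len(pts) - displaced.size
        assert not np.intersect1d(kept.grid_index,
                                  reference.grid_index[displaced]).size

    def test_zero_cutoff_is_tracking_loss(self, reference):
        shifted = PointCloud(reference.points + 1.0)
        with pytest.raises(TrackingLossError):
            remove_distant_outliers(shifted, reference, 1e-9, I)

    def test_order_preserved(self, reference):
        kept = remove_distant_outliers(reference, reference, 5.0, I)
        assert np.all(np.diff(kept.grid_index) > 0)

    def test_undersample_stride(self):
        cloud = PointCloud(np.arange(999 * 3, dtype=float).reshape(-1, 3))
        assert len(grid_undersample(cloud, 1)) == 999
        assert len(grid_undersample(cloud, 3)) == 333
        assert len(grid_undersample(cloud, 5000)) == 1

    def test_undersample_follows_grid_order(self, rng):
        pts = rng.normal(size=(30, 3))
        gidx = rng.permutation(1000)[:30]
        cloud = PointCloud(pts, grid_index=gidx)
        sub = grid_undersample(cloud, 3)
        expected = np.sort(np.argsort(gidx, kind="stable")[::3])
        np.testing.assert_array_equal(sub.points, pts[expected])


class TestRegister:
    def test_self_registration_is_identity(self, reference, ball):
        res = register(reference, reference, config=RobustConfig(), ball=ball)
        assert hpd(res.transform, I, ball) < 1e-9
        assert np.all(res.per_point_weight == 1.0)

    def test_known_pose_recovered_noise_free(self, reference, ball):
        T = compose(RigidTransform.from_translation([1.0, 0.5, -0.8]),
                    RigidTransform.from_rotvec([0.010, 0.005, -0.008]))
        frame = PointCloud(invert(T).apply(reference.points),
                           grid_index=reference.grid_index)
        res = register(frame, reference, config=RobustConfig(), ball=ball)
        assert hpd(res.transform, T, ball) < 1e-3

    def test_objective_nonincreasing_within_inner_solves(self, reference,
                                                         ball, rng):
        T = random_transform(rng)
        frame = PointCloud(
            invert(T).apply(reference.points) + rng.normal(0, 0.1, reference.points.shape),
            grid_index=reference.grid_index)
        res = register(frame, reference, config=RobustConfig(), ball=ball)
        for before, after in res.objective_history:
            assert after <= before + 1e-9 * max(1.0, abs(before))

    def test_equivariance_under_frame_transformation(self, reference, ball):
        rng = np.random.default_rng(3)
        cfg = RobustConfig()
        base = PointCloud(reference.points + rng.normal(0, 0.05,
                                                        reference.points.shape),
                          grid_index=reference.grid_index)
        res0 = register(base, reference, config=cfg, ball=ball)
        for _ in range(5):
            G = random_transform(rng, 2.0, np.deg2rad(2.0))
            moved = PointCloud(G.apply(base.points),
                               grid_index=base.grid_index)
            res = register(moved, reference, init=compose(res0.transform,
                                                          invert(G)),
                           config=cfg, ball=ball)
            # frame transformed by G => recovered pose composes with G⁻¹
            assert hpd(res.transform, compose(res0.transform, invert(G)),
                       ball) < 0.02

    def test_outlier_contrast_huber_vs_identity(self, reference, ball):
        # 20% uniform outliers in the 30 mm-inflated box; the robust
        # criterion must shrug them off while plain least squares cannot.
        T = compose(RigidTransform.from_translation([1.0, 0.5, -0.8]),
                    RigidTransform.from_rotvec([0.010, 0.005, -0.008]))
        rng = np.random.default_rng(17)
        pts = invert(T).apply(reference.points)
        pts += rng.normal(0, 0.1, pts.shape)
        n_out = int(round(0.2 * pts.shape[0] / 0.8))
        out = rng.uniform(pts.min(0) - 30, pts.max(0) + 30, (n_out, 3))
        frame = grid_undersample(PointCloud(np.vstack([pts, out])), 3)
        err = {}
        for kind in ("huber", "identity"):
            cfg = RobustConfig(criterion=kind)
            res = register(frame, reference, config=cfg, ball=ball,
                           preprocess=False)
            err[kind] = hpd(res.transform, T, ball)
        assert err["huber"] < 0.1
        assert err["identity"] >= 5 * err["huber"]

    def test_too_few_points_is_tracking_loss(self, reference):
        tiny = PointCloud(reference.points[:2], timestamp=4.5)
        with pytest.raises(TrackingLossError) as exc:
            register(tiny, reference, preprocess=False)
        assert exc.value.timestamp == 4.5

    def test_determinism(self, reference, ball, rng):
        frame = PointCloud(reference.points + rng.normal(0, 0.1,
                                                         reference.points.shape),
                           grid_index=reference.grid_index)
        r1 = register(frame, reference, config=RobustConfig(), ball=ball)
        r2 = register(frame, reference, config=RobustConfig(), ball=ball)
        assert np.array_equal(r1.transform.rotation, r2.transform.rotation)
        assert np.array_equal(r1.transform.translation,
                              r2.transform.translation)
        assert np.array_equal(r1.per_point_weight, r2.per_point_weight)


class TestTrackSequence:
    def test_static_frames_stay_at_identity(self, reference, ball):
        cfg = ScenarioConfig(seed=2, duration=3.0, noise_sd=0.05,
                             breathing_amplitude=0.0,
                             rot_walk_step_disp_sd=0.0)
        truth = make_truth_trace(cfg, ball=ball)
        frames = render_frames(reference, truth, cfg)
        trace, results = track_sequence(frames, reference,
                                        config=RobustConfig(), ball=ball)
        assert trace.valid.all()
        for i in range(len(trace)):
            assert hpd(trace.pose(i), I, ball) < 0.02  # noise floor

    def test_breathing_motion_recovered(self, reference, ball):
        cfg = ScenarioConfig(seed=6, duration=20.0, noise_sd=0.05,
                             breathing_amplitude=0.1,
                             rot_walk_step_disp_sd=0.0)
        truth = make_truth_trace(cfg, ball=ball)
        frames = render_frames(reference, truth, cfg)
        trace, _ = track_sequence(frames, reference, config=RobustConfig(),
                                  ball=ball)
        expected = truth.trace(trace.times)
        for axis in (1, 2):  # breathing axis has y and z components
            r = np.corrcoef(trace.translations[:, axis],
                            expected.translations[:, axis])[0, 1]
            assert r > 0.99

    def test_tracking_loss_marks_pose_missing_and_resumes(self, reference,
                                                          ball):
        cfg = ScenarioConfig(seed=2, duration=2.0, noise_sd=0.05,
                             breathing_amplitude=0.0,
                             rot_walk_step_disp_sd=0.0)
        truth = make_truth_trace(cfg, ball=ball)
        frames = render_frames(reference, truth, cfg)
        # frame 5 is garbage far from the reference: unregisterable
        bad = PointCloud(frames[5].points + 500.0,
                         timestamp=frames[5].timestamp)
        frames[5] = bad
        trace, results = track_sequence(frames, reference,
                                        config=RobustConfig(), ball=ball)
        assert not trace.valid[5] and results[5] is None
        assert trace.valid[6]
        assert hpd(trace.pose(6), I, ball) < 0.02

    def test_majority_failure_raises(self, reference):
        frames = [PointCloud(reference.points + 500.0, timestamp=float(k))
                  for k in range(4)]
        with pytest.raises(TrackingLossError):
            track_sequence(frames, reference, config=RobustConfig())

    def test_unordered_timestamps_rejected(self, reference):
        frames = [PointCloud(reference.points, timestamp=1.0),
                  PointCloud(reference.points, timestamp=0.5)]
        with pytest.raises(ValueError):
            track_sequence(frames, reference)
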