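import numpy as np
import pytest

from btk.errors import DegenerateGeometryError, InputError
from btk.gait_kinematics import (
    NOISY_DETECTOR,
    build_centerline,
    centerline_anchors,
    compare_annotations,
    detect_reversals,
    detect_swings,
    detect_turns,
    duty_factor,
    fisher_combine_pvalues,
    fisher_z_mean,
    intervals_to_frames,
    odortaxis_success,
    preprocess_pose,
    straighten,
    straighten_track,
    swing_series,
    velocity_from_stage,
)
from btk.io_core import PoseTrack
from btk.synthetic_data import Trajectory


def track_from_xy(x, y, likelihood=None, parts=None, pixel_size=1.0):
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    parts = parts or tuple(f"p{i}" for i in range(p))
    lk = np.ones_like(x) if likelihood is None else np.asarray(likelihood, dtype=float)
    return PoseTrack(
        frame_index=np.arange(n), time=np.arange(n, dtype=float), parts=parts,
        x=x, y=np.asarray(y, dtype=float), likelihood=lk, pixel_size=pixel_size,
    )


class TestPreprocess:
    def test_low_likelihood_interpolated_linearly(self):
        track = track_from_xy(
            [[0.0], [7.0], [2.0]], [[0.0], [0.0], [0.0]],
            likelihood=[[0.9], [0.5], [0.9]],
        )
        cleaned, _ = preprocess_pose(track)
        assert cleaned.x[1, 0] == pytest.approx(1.0)

    def test_high_likelihood_track_unchanged(self, rng):
        x = rng.uniform(0, 10, (5, 3))
        track = track_from_xy(x, x + 1)
        cleaned, _ = preprocess_pose(track)
        np.testing.assert_array_equal(cleaned.x, x)

    def test_center_of_mass(self):
        track = track_from_xy([[0.0, 2.0]], [[0.0, 2.0]])
        with pytest.raises(InputError):
            preprocess_pose(track)  # single frame
        track2 = track_from_xy([[0.0, 2.0], [0.0, 2.0]], [[0.0, 2.0], [0.0, 2.0]])
        _, com = preprocess_pose(track2)
        np.testing.assert_allclose(com, [[1.0, 1.0], [1.0, 1.0]])

    def test_part_always_below_threshold_named(self):
        track = track_from_xy(
            np.ones((4, 2)), np.ones((4, 2)),
            likelihood=np.column_stack([np.ones(4), np.full(4, 0.1)]),
            parts=("good", "bad"),
        )
        with pytest.raises(InputError, match="bad"):
            preprocess_pose(track)


class TestCenterline:
    def test_collinear_anchors_equally_spaced(self):
        anchors = np.array([[0.0, 0.0], [30.0, 0.0], [100.0, 0.0]])
        cl = build_centerline(anchors, n_points=51)
        np.testing.assert_allclose(cl[:, 1], 0.0)
        np.testing.assert_allclose(np.diff(cl[:, 0]), 2.0, atol=1e-9)

    def test_quarter_circle_arc_length_within_two_percent(self):
        theta = np.linspace(0, np.pi / 2, 6)
        anchors = 100.0 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        cl = build_centerline(anchors, n_points=100)
        arc = np.linalg.norm(np.diff(cl, axis=0), axis=1).sum()
        assert abs(arc - 100 * np.pi / 2) / (100 * np.pi / 2) < 0.02

    def test_coincident_anchors_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            build_centerline(np.zeros((3, 2)))
        with pytest.raises(DegenerateGeometryError):
            build_centerline(np.array([[1.0, 1.0]]))

    def test_anchor_extraction_orders_pairs_anterior_first(self):
        parts = ("front", "leg2_left", "leg2_right", "leg1_left", "leg1_right", "rear")
        x = np.array([[0.0, 20.0, 20.0, 10.0, 10.0, 30.0]])
        y = np.array([[0.0, 5.0, -5.0, 3.0, -3.0, 0.0]])
        track = track_from_xy(x, y, parts=parts)
        anchors = centerline_anchors(track, 0)
        np.testing.assert_allclose(anchors[:, 0], [0.0, 10.0, 20.0, 30.0])
        np.testing.assert_allclose(anchors[:, 1], 0.0)


class TestStraighten:
    def test_straight_body_ap_and_lateral(self):
        cl = np.stack([np.linspace(0, 100, 101), np.zeros(101)], axis=1)
        ap, lat = straighten(np.array([[30.0, 4.0]]), cl)
        assert ap[0] == pytest.approx(30.0)
        assert lat[0] == pytest.approx(4.0)

    def test_point_on_centerline_zero_lateral(self):
        cl = np.stack([np.linspace(0, 50, 51), np.zeros(51)], axis=1)
        _, lat = straighten(np.array([[17.3, 0.0]]), cl)
        assert lat[0] == pytest.approx(0.0, abs=1e-9)

    def test_quarter_circle_ap_tracks_arc_parameter(self):
        theta = np.linspace(0, np.pi / 2, 200)
        cl = 100.0 * np.stack([np.sin(theta), 1 - np.cos(theta)], axis=1)
        for frac in (0.25, 0.5, 0.75):
            th = frac * np.pi / 2
            pt = 100.0 * np.array([[np.sin(th), 1 - np.cos(th)]])
            ap, _ = straighten(pt, cl)
            assert abs(ap[0] - 100.0 * th) / (100.0 * th) < 0.02

    def test_rigid_motion_invariance(self, rng):
        cl = np.stack([np.linspace(0, 80, 100), 5 * np.sin(np.linspace(0, 3, 100))], axis=1)
        pts = rng.uniform(0, 80, (6, 2))
        ap0, d0 = straighten(pts, cl)
        angle = 0.7
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        shift = np.array([12.0, -4.0])
        ap1, d1 = straighten(pts @ rot.T + shift, cl @ rot.T + shift)
        np.testing.assert_allclose(ap1, ap0, atol=1e-9)
        np.testing.assert_allclose(d1, d0, atol=1e-9)


class TestSwingsAndDuty:
    def test_constant_series_no_swings(self):
        assert detect_swings(np.full(300, 5.0), 30.0) == []

    def test_noise_free_recovery_within_one_frame(self, clean_gait):
        params, track, truth = clean_gait
        cleaned, _ = preprocess_pose(track)
        sp = straighten_track(cleaned)
        for leg in truth.extras["leg_names"][:4]:
            detected = detect_swings(swing_series(sp, leg), params.frame_rate)
            for t_on, t_off in truth.swing_intervals[leg]:
                best = min(detected, key=lambda iv: abs(iv[0] - t_on))
                assert abs(best[0] - t_on) <= 1 and abs(best[1] - t_off) <= 1

    def test_noise_free_duty_recovery(self, clean_gait):
        params, track, truth = clean_gait
        cleaned, _ = preprocess_pose(track)
        sp = straighten_track(cleaned)
        duties = [
            duty_factor(detect_swings(swing_series(sp, leg), params.frame_rate))
            for leg in truth.extras["leg_names"]
        ]
        assert abs(np.nanmean(duties) - params.duty_factor) <= 0.02

    def test_duty_stance_six_of_ten(self):
        # swing 4 frames, stride 10 -> stance 6, duty 0.6
        intervals = [(0, 4), (10, 14), (20, 24)]
        assert duty_factor(intervals) == pytest.approx(0.6)

    def test_duty_all_swing_is_zero(self):
        assert duty_factor([(0, 10), (10, 20)]) == pytest.approx(0.0)

    def test_no_complete_stride_is_nan(self):
        assert np.isnan(duty_factor([(3, 7)]))

    def test_duty_plus_swing_fraction_is_one(self, clean_gait):
        params, track, truth = clean_gait
        for ivs in truth.swing_intervals.values():
            for (on0, off0), (on1, _) in zip(ivs[:-1], ivs[1:]):
                stride, swing = on1 - on0, off0 - on0
                assert (1 - swing / stride) + swing / stride == pytest.approx(1.0)


class TestAgreement:
    def test_self_agreement_perfect(self):
        ivs = [(10, 20), (40, 52), (70, 85)]
        rep = compare_annotations(ivs, ivs, n_frames=100)
        assert rep.accuracy == 1.0 and rep.precision == 1.0
        assert np.all(rep.onset_deltas == 0) and np.all(rep.offset_deltas == 0)
        assert rep.r == pytest.approx(1.0)

    def test_hand_confusion_counts(self):
        # manual swing frames 10-19, auto 12-21, of 100 frames
        rep = compare_annotations([(12, 22)], [(10, 20)], n_frames=100)
        assert rep.accuracy == pytest.approx(0.96)
        assert rep.precision == pytest.approx(0.8)

    def test_length_mismatch_frames(self):
        fa = intervals_to_frames([(2, 5)], 10)
        assert fa.sum() == 3 and fa[2] and not fa[5]

    def test_fisher_combine_printed_example(self):
        chi2, df, p = fisher_combine_pvalues([0.1, 0.1])
        assert chi2 == pytest.approx(9.2103, abs=1e-3)
        assert df == 4
        # chi2 survival for df=4: exp(-x/2)(1+x/2)
        assert p == pytest.approx(np.exp(-chi2 / 2) * (1 + chi2 / 2), rel=1e-9)
        assert p == pytest.approx(0.056, abs=0.001)

    def test_fisher_z_identity_on_equal_correlations(self):
        for r in (-0.5, 0.0, 0.42, 0.96):
            assert fisher_z_mean([r, r, r]) == pytest.approx(r, abs=1e-12)


class TestTrajectoryBehaviors:
    def test_velocity_stationary_zero(self):
        t = np.arange(10) / 30.0
        assert velocity_from_stage(t, np.ones(10), np.ones(10)).max() < 1e-9

    def test_velocity_five_mm_per_sample(self):
        # 5 mm in 1/30 s = 150 mm/s = 1.5e5 µm/s at that step
        t = np.array([0.0, 1 / 30.0])
        v = velocity_from_stage(t, np.array([0.0, 5.0]), np.zeros(2))
        assert v[0] == pytest.approx(150_000.0)

    def test_velocity_constant_speed_path(self):
        t = np.arange(0, 10, 1 / 30.0)
        v = velocity_from_stage(t, 1.0 * t, np.zeros_like(t))  # 1 mm/s
        assert abs(v.mean() - 1000.0) < 10.0

    def test_straight_path_no_reversals_no_turns(self):
        t = np.arange(0, 10, 0.1)
        traj = Trajectory(t, t, np.zeros_like(t))
        assert detect_reversals(traj) == []
        assert detect_turns(traj) == []

    def test_out_and_back_single_reversal(self):
        t = np.arange(0, 10, 0.05)
        x = np.where(t < 5, t, 10 - t)
        traj = Trajectory(t, x, np.zeros_like(t))
        revs = detect_reversals(traj)
        assert len(revs) == 1
        assert revs[0][0] - 1.0 <= 5.0 <= revs[0][1] + 1.0

    def test_slow_circle_below_threshold(self):
        t = np.arange(0, 60, 0.1)
        omega = 2 * np.pi / 60  # one lap per minute: ~12 deg per 2 s window
        traj = Trajectory(t, np.cos(omega * t), np.sin(omega * t))
        assert detect_reversals(traj) == []
        assert detect_turns(traj) == []

    def test_right_angle_corner_is_a_turn(self):
        t = np.arange(0, 10, 0.05)
        x = np.where(t < 5, t, 5.0)
        y = np.where(t < 5, 0.0, t - 5)
        turns = detect_turns(Trajectory(t, x, y))
        assert len(turns) == 1
        assert abs(abs(turns[0][2]) - 90.0) < 15.0

    def test_hairpin_is_reversal_not_turn(self):
        angle = np.deg2rad(170.0)
        t = np.arange(0, 10, 0.05)
        x = np.where(t < 5, t, 5 + (t - 5) * np.cos(np.pi - angle) * -1)
        # construct: incoming heading 0 deg, outgoing heading 170 deg
        out_dir = np.array([np.cos(np.deg2rad(170.0)), np.sin(np.deg2rad(170.0))])
        x = np.where(t < 5, t, 5 + (t - 5) * out_dir[0])
        y = np.where(t < 5, 0.0, (t - 5) * out_dir[1])
        traj = Trajectory(t, x, y)
        assert len(detect_reversals(traj)) == 1
        assert detect_turns(traj) == []

    def test_gait_diagram_renders_stance_bars(self):
        import matplotlib

        matplotlib.use("Agg")
        from btk.gait_kinematics import SwingAnnotation, gait_diagram

        ann = SwingAnnotation({"leg1": [(5, 15)], "leg2": [(20, 30)]}, 30.0, 60)
        ax = gait_diagram(ann)
        assert len(ax.collections) > 0

    def test_odortaxis_success_rules(self):
        t = np.arange(0, 100, 0.5)
        approach = Trajectory(t, np.maximum(50 - t, 0.0), np.zeros_like(t))
        assert odortaxis_success(approach, (0.0, 0.0))
        # enters then leaves again before the end
        x = np.abs(50 - t)
        assert not odortaxis_success(Trajectory(t, x, np.zeros_like(t)), (0.0, 0.0))
        far = Trajectory(t, 50 + t, np.zeros_like(t))
        assert not odortaxis_success(far, (0.0, 0.0))
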