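import math

import numpy as np
import pytest

from sidegait.background import largest_silhouette
from sidegait.depth_core import FrameSequence, PixelCoord
from sidegait.errors import TrackingError
from sidegait.frontpose import BodyModel
from sidegait.sideview import (JOINT_NAMES, _reproject, hip_sweep_angles,
                               locate_elbow_side, locate_head_side,
                               locate_hip_side, locate_knee_side,
                               locate_shoulder_side, near_side_region,
                               segment_overlap, track_frame, track_sequence)
from sidegait.validation import diff_statistics


def small_model(**overrides):
    base = dict(human_height=170, head_height=24, shift_row=10, c=3.4,
                R=7.1, hs_dist=20, se_dist=25, ew_dist=24, ak_dist=30,
                kh_dist=46, subject_depth=2750.0)
    base.update(overrides)
    return BodyModel(**base)


def sil_from(mask):
    return largest_silhouette(mask.astype(np.uint8))


def wall(depth=3300, shape=(240, 320)):
    return np.full(shape, depth, dtype=np.int32)


class TestLocateHeadSide:
    def test_row_arithmetic(self):
        mask = np.zeros((240, 320), dtype=np.uint8)
        mask[25:200, 140:161] = 1
        pt = locate_head_side(sil_from(mask), small_model())
        assert pt.row == 35

    def test_column_mean(self):
        mask = np.zeros((240, 320), dtype=np.uint8)
        mask[25:200, 140:161] = 1  # cols 140..160
        pt = locate_head_side(sil_from(mask), small_model())
        assert pt.col == 150


class TestNearSideRegion:
    def _legs(self, near=2500, far=2650):
        df = wall()
        mask = np.zeros((240, 320), dtype=np.uint8)
        df[100:230, 100:115] = near
        mask[100:230, 100:115] = 1
        df[100:230, 130:145] = far
        mask[100:230, 130:145] = 1
        df[95:100, 100:145] = far  # pelvis bridge keeping one component
        mask[95:100, 100:145] = 1
        return df, sil_from(mask)

    def test_near_leg_only(self):
        df, sil = self._legs()
        region = near_side_region(df, sil, small_model())
        assert region.bits[150, 105]
        assert not region.bits[150, 135]
        assert abs(region.reference_depth - 2500) < 40

    def test_single_leg_whole(self):
        df = wall()
        mask = np.zeros((240, 320), dtype=np.uint8)
        df[100:230, 100:115] = 2500
        mask[100:230, 100:115] = 1
        region = near_side_region(df, sil_from(mask), small_model())
        np.testing.assert_array_equal(region.bits, mask.astype(bool))

    def test_noise_spike_center_rejected(self):
        df, sil = self._legs()
        # the minimal-depth pixel on the probe row is a lone 200-mm spike
        base_row = sil.last_row - small_model().ak_dist // 2
        df[base_row, 107] = 2300
        region = near_side_region(df, sil, small_model())
        assert region.bits[150, 105]          # near leg retained
        assert abs(region.reference_depth - 2500) < 40
        assert not region.bits[base_row, 107]  # spike outside the gap

    def test_legs_closer_than_gap_merge(self):
        df, sil = self._legs(near=2500, far=2560)
        region = near_side_region(df, sil, small_model())
        assert region.bits[150, 105] and region.bits[150, 135]

    def test_no_valid_pixels_raises(self):
        df = wall()
        mask = np.zeros((240, 320), dtype=np.uint8)
        mask[100:230, 100:115] = 1  # silhouette but df reads 0 there
        df[100:230, 100:115] = 0
        with pytest.raises(TrackingError):
            near_side_region(df, sil_from(mask), small_model())


class TestReproject:
    def test_vertical(self):
        assert _reproject(PixelCoord(10, 50), PixelCoord(40, 50), 20) \
            == PixelCoord(30, 50)

    def test_double_distance_normalized(self):
        # provisional at 2x the target length along a 3-4-5 direction
        got = _reproject(PixelCoord(0, 0), PixelCoord(60, 80), 50)
        assert got == PixelCoord(30, 40)

    def test_anchor_equals_target(self):
        p = PixelCoord(5, 5)
        assert _reproject(p, p, 17) == p


class TestLocateShoulderSide:
    def test_vertical_alignment(self):
        mask = np.zeros((240, 320), dtype=np.uint8)
        mask[30:200, 155:166] = 1
        head = PixelCoord(40, 160)
        model = small_model(hs_dist=20)
        assert locate_shoulder_side(sil_from(mask), head, model) \
            == PixelCoord(60, 160)

    def test_distance_equals_hs_dist(self):
        mask = np.zeros((240, 320), dtype=np.uint8)
        for r in range(30, 200):
            mask[r, 100 + r // 2:140 + r // 2] = 1  # slanted torso
        head = PixelCoord(40, 135)
        model = small_model(hs_dist=25)
        pt = locate_shoulder_side(sil_from(mask), head, model)
        assert abs(head.distance_to(pt) - 25) <= 1.0

    def test_empty_row_raises(self):
        mask = np.zeros((240, 320), dtype=np.uint8)
        mask[30:50, 155:166] = 1
        with pytest.raises(TrackingError):
            locate_shoulder_side(sil_from(mask), PixelCoord(40, 160),
                                 small_model(hs_dist=50))


class TestLocateKneeSide:
    def test_vertical_shank(self):
        df = wall()
        mask = np.zeros((240, 320), dtype=np.uint8)
        df[120:231, 100:113] = 2500
        mask[120:231, 100:113] = 1
        model = small_model(ak_dist=30)
        region = near_side_region(df, sil_from(mask), model)
        knee = locate_knee_side(region, PixelCoord(220, 106), model)
        assert knee == PixelCoord(190, 106)

    def test_distance_equals_ak_dist_when_flexed(self):
        df = wall()
        mask = np.zeros((240, 320), dtype=np.uint8)
        for r in range(120, 231):
            offset = (230 - r) // 2  # shank leaning sideways
            df[r, 100 + offset:113 + offset] = 2500
            mask[r, 100 + offset:113 + offset] = 1
        model = small_model(ak_dist=30)
        region = near_side_region(df, sil_from(mask), model)
        ankle = PixelCoord(220, 111)
        knee = locate_knee_side(region, ankle, model)
        assert abs(ankle.distance_to(knee) - 30) <= 1.0


class TestSegmentOverlap:
    @staticmethod
    def _naive_line(r0, c0, r1, c1):
        # independent pure-python walk along the major axis, rounding the
        # minor coordinate half-up (the documented raster convention)
        n = max(abs(r1 - r0), abs(c1 - c0))
        if n == 0:
            return [(r0, c0)]
        points = []
        for i in range(n + 1):
            r = math.floor(r0 + i * (r1 - r0) / n + 0.5)
            c = math.floor(c0 + i * (c1 - c0) / n + 0.5)
            points.append((r, c))
        return points

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        from sidegait.depth_core import round_half_up
        for _ in range(120):
            mask = rng.random((40, 40)) < 0.4
            anchor = PixelCoord(int(rng.integers(5, 35)),
                                int(rng.integers(5, 35)))
            theta = rng.uniform(0, 2 * math.pi)
            length = rng.uniform(3, 25)
            direction = (math.sin(theta), math.cos(theta))
            got = segment_overlap(anchor, direction, length, mask)
            er = anchor.row + round_half_up(length * direction[0])
            ec = anchor.col + round_half_up(length * direction[1])
            want = sum(1 for r, c in self._naive_line(anchor.row, anchor.col,
                                                      er, ec)
                       if 0 <= r < 40 and 0 <= c < 40 and mask[r, c])
            assert got == want


class TestLocateElbowSide:
    def _arm_frame(self, angle_deg=0.0, half_width=1):
        df = wall()
        mask = np.zeros((240, 320), dtype=np.uint8)
        shoulder = PixelCoord(60, 160)
        rad = math.radians(angle_deg)
        for t in range(0, 45):
            r = shoulder.row + int(round(t * math.cos(rad)))
            c = shoulder.col + int(round(t * math.sin(rad)))
            df[r, c - half_width:c + half_width + 1] = 2500
            mask[r, c - half_width:c + half_width + 1] = 1
        return df, sil_from(mask), shoulder

    def test_straight_down_arm(self):
        df, sil, shoulder = self._arm_frame(0.0)
        model = small_model(se_dist=25)
        elbow = locate_elbow_side(df, sil, shoulder, model)
        # 2-degree quantization plus the smaller-angle tie rule allow 1 px
        assert abs(elbow.col - shoulder.col) <= 1
        assert elbow.row == shoulder.row + 25

    def test_tilted_arm_follows_direction(self):
        df, sil, shoulder = self._arm_frame(15.0, half_width=4)
        model = small_model(se_dist=25)
        elbow = locate_elbow_side(df, sil, shoulder, model)
        angle = math.degrees(math.atan2(elbow.col - shoulder.col,
                                        elbow.row - shoulder.row))
        assert abs(angle - 15.0) <= 8.0

    def test_symmetric_region_prefers_smaller_theta(self):
        # uniform square region symmetric about the shoulder column: the
        # theta<90 candidate ties its mirror and must win
        df = wall()
        mask = np.zeros((240, 320), dtype=np.uint8)
        df[60:120, 130:191] = 2500
        mask[60:120, 130:191] = 1
        shoulder = PixelCoord(60, 160)
        elbow = locate_elbow_side(df, sil_from(mask), shoulder,
                                  small_model(se_dist=25))
        assert elbow.col >= shoulder.col

    def test_tiny_arm_region_raises(self):
        df = wall()
        mask = np.zeros((240, 320), dtype=np.uint8)
        df[60:62, 160:162] = 2500
        mask[60:62, 160:162] = 1
        with pytest.raises(TrackingError):
            locate_elbow_side(df, sil_from(mask), PixelCoord(60, 160),
                              small_model(se_dist=25))


class TestLocateHipSide:
    def _leg(self, thigh_toward="up"):
        df = wall()
        mask = np.zeros((240, 320), dtype=np.uint8)
        knee = PixelCoord(170, 150)
        # shank below the knee
        df[170:231, 144:157] = 2500
        mask[170:231, 144:157] = 1
        if thigh_toward == "up":
            df[110:171, 144:157] = 2500
            mask[110:171, 144:157] = 1
        else:  # horizontal thigh toward the rear (+cols)
            df[158:171, 150:220] = 2500
            mask[158:171, 150:220] = 1
        return df, sil_from(mask), knee

    def test_standing_hip_above_knee(self):
        df, sil, knee = self._leg("up")
        model = small_model(kh_dist=46)
        region = near_side_region(df, sil, model)
        hip = locate_hip_side(region, knee, model)
        assert abs(hip.col - knee.col) <= 5
        assert hip.row <= knee.row - 40

    def test_seated_hip_horizontal(self):
        df, sil, knee = self._leg("horizontal")
        model = small_model(kh_dist=46)
        region = near_side_region(df, sil, model)
        hip = locate_hip_side(region, knee, model)
        assert hip.col - knee.col >= 40     # displaced toward the rear
        assert abs(hip.row - knee.row) <= 15

    def test_distance_is_kh_dist_by_construction(self):
        df, sil, knee = self._leg("up")
        model = small_model(kh_dist=46)
        region = near_side_region(df, sil, model)
        hip = locate_hip_side(region, knee, model)
        assert abs(knee.distance_to(hip) - 46) <= 1.0

    def test_sweep_covers_upper_half_plane_only(self):
        angles = hip_sweep_angles()
        for gamma in angles:
            assert -math.cos(math.radians(gamma)) <= math.sin(math.radians(2))
        assert angles[0] == 4
        assert len(angles) == len(set(angles))


class TestTrackSequence:
    def test_reprojection_invariants_every_frame(self, gugt_short,
                                                 clean_background,
                                                 calibrated):
        seq, _ = gugt_short
        model, _ = calibrated
        traj = track_sequence(seq, clean_background, model)
        for k in range(traj.n_frames):
            head = traj.joints["head"][k]
            shoulder = traj.joints["shoulder"][k]
            if head is not None and shoulder is not None:
                d = math.hypot(head[0] - shoulder[0], head[1] - shoulder[1])
                assert abs(d - model.hs_dist) <= 1.0
            ankle = traj.joints["ankle"][k]
            knee = traj.joints["knee"][k]
            if ankle is not None and knee is not None:
                d = math.hypot(ankle[0] - knee[0], ankle[1] - knee[1])
                assert abs(d - model.ak_dist) <= 1.0

    def test_deterministic(self, gugt_short, clean_background, calibrated):
        seq, _ = gugt_short
        model, _ = calibrated
        a = track_sequence(seq, clean_background, model)
        b = track_sequence(seq, clean_background, model)
        assert a.joints == b.joints

    def test_identical_frames_identical_joints(self, gugt_short,
                                               clean_background, calibrated):
        seq, _ = gugt_short
        model, _ = calibrated
        repeated = FrameSequence([seq[20]] * 3)
        traj = track_sequence(repeated, clean_background, model)
        for track in traj.joints.values():
            assert track[0] == track[1] == track[2]

    def test_background_only_all_missing(self, clean_background, calibrated):
        model, _ = calibrated
        seq = FrameSequence([clean_background] * 3)
        traj = track_sequence(seq, clean_background, model)
        for track in traj.joints.values():
            assert all(p is None for p in track)

    def test_mean_error_below_8px(self, gugt_short, clean_background,
                                  calibrated):
        seq, ref = gugt_short
        model, _ = calibrated
        traj = track_sequence(seq, clean_background, model)
        stats = diff_statistics(traj, ref, compensate=False)
        for joint in JOINT_NAMES:
            assert stats[joint].n_valid == len(seq)
            assert stats[joint].mu <= 8.0, joint

    def test_noise_degrades_by_at_most_3px(self, scene_cfg, figure,
                                           clean_background, calibrated):
        from sidegait.synthdepth import SceneConfig, simulate_gugt
        model, _ = calibrated
        clean_seq, ref = simulate_gugt(scene_cfg, figure, n_frames=30, seed=9)
        noisy_cfg = SceneConfig(noise_sigma=10.0)
        noisy_seq, _ = simulate_gugt(noisy_cfg, figure, n_frames=30, seed=9)
        base = diff_statistics(track_sequence(clean_seq, clean_background,
                                              model), ref)
        noisy = diff_statistics(track_sequence(noisy_seq, clean_background,
                                               model), ref)
        for joint in JOINT_NAMES:
            assert noisy[joint].mu - base[joint].mu <= 3.0, joint


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path):
        from sidegait.sideview import Trajectory
        traj = Trajectory(joints={
            "head": [(1.0, 2.0), None, (3.0, 4.0)],
            "knee": [None, (5.0, 6.0), (7.0, 8.0)]})
        traj.save_csv(tmp_path / "t.csv")
        back = Trajectory.load_csv(tmp_path / "t.csv")
        assert back.joints == traj.joints

    def test_interpolation_fills_gaps(self):
        from sidegait.sideview import Trajectory
        traj = Trajectory(joints={"head": [(0.0, 0.0), None, (2.0, 4.0)]})
        filled = traj.interpolated()
        assert filled.joints["head"][1] == (1.0, 2.0)
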