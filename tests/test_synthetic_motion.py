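"""Synthetic trajectory generator: waveforms, inverse kinematics, ground
truth, noise and dropout models."""

import math

import numpy as np
import pytest

from mdlkit import builtin, run
from mdlkit.pose_model import angles_from_frame, com_height
from mdlkit.synthetic_motion import (InfeasiblePoseError, MotionSpec,
                                     Posture, angle_waveform,
                                     generate_trajectory, inject_dropout,
                                     pose_from_angles, recipe)


class TestAngleWaveform:
    def test_endpoints_and_extreme(self):
        w = angle_waveform(175.0, 85.0, 40)
        assert w[0] == 175.0 and w[-1] == 175.0
        assert w.min() == 85.0
        assert np.argmin(w) == pytest.approx(20, abs=1)

    def test_minimal_four_frame_cycle_crosses_thresholds(self):
        w = angle_waveform(175.0, 85.0, 4)
        assert len(w) == 4
        assert w.min() == 85.0 and w.max() == 175.0

    def test_low_start_variant_peaks_mid_cycle(self):
        w = angle_waveform(170.0, 88.0, 41, start="low")
        assert w[0] == 88.0 and w[-1] == 88.0 and w.max() == 170.0

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            angle_waveform(85.0, 175.0, 40)
        with pytest.raises(ValueError):
            angle_waveform(175.0, 85.0, 3)


class TestPoseFromAngles:
    @pytest.mark.parametrize("targets,posture", [
        ({"knee_angle": 180.0, "torso_angle": 178.0}, Posture()),
        ({"knee_angle": 90.0, "hip_angle": 100.0}, Posture()),
        ({"torso_angle": 88.0, "elbow_angle": 172.0},
         Posture(lean=50.0, arm_elevation=0.3)),
        ({"elbow_angle": 63.0, "shoulder_angle": 63.0},
         Posture(arm_elevation=0.18)),
        ({"elbow_angle": 86.0, "torso_angle": 170.0},
         Posture(template="horizontal")),
        ({"elbow_angle": 58.0, "torso_angle": 170.0},
         Posture(template="hang")),
    ])
    def test_targets_recovered_within_a_degree(self, targets, posture):
        fr = pose_from_angles(targets, posture)
        av = angles_from_frame(fr)
        for k, v in targets.items():
            assert av.get(k) == pytest.approx(v, abs=1.0)

    def test_squat_bottom_sits_lower_than_standing(self):
        stand = pose_from_angles({"knee_angle": 175.0})
        deep = pose_from_angles({"knee_angle": 90.0})
        assert com_height(deep) > com_height(stand)  # y grows downward

    def test_deterministic(self):
        t = {"knee_angle": 120.0, "hip_angle": 130.0}
        a = pose_from_angles(t)
        b = pose_from_angles(t)
        assert a == b

    def test_all_landmarks_present_and_in_unit_square(self):
        fr = pose_from_angles({"knee_angle": 90.0, "hip_angle": 95.0})
        assert all(p is not None for p in fr.points)
        assert all(0.0 <= p.x <= 1.0 and 0.0 <= p.y <= 1.0
                   for p in fr.points)

    def test_infeasible_combinations_rejected(self):
        with pytest.raises(InfeasiblePoseError):
            pose_from_angles({"knee_angle": 200.0})
        with pytest.raises(InfeasiblePoseError):
            pose_from_angles({"hip_angle": 90.0, "torso_angle": 90.0})
        with pytest.raises(InfeasiblePoseError):
            pose_from_angles({"wrist_angle": 90.0})


class TestGenerateTrajectory:
    def test_window_labels_and_length_consistency(self):
        traj, gt = generate_trajectory(MotionSpec(exercise="squat", reps=3,
                                                  seed=0))
        assert len(gt.labels) == len(traj)
        assert len(gt.rep_windows) == 3
        a, b = gt.rep_windows[0]
        assert set(gt.labels[a:b + 1]) == {1, 2}

    def test_zero_reps_is_standing_only(self):
        traj, gt = generate_trajectory(MotionSpec(exercise="squat", reps=0))
        assert gt.rep_windows == ()
        assert run(traj, builtin("squat"))[0] == 0

    def test_seeded_determinism_is_bitwise(self):
        spec = MotionSpec(exercise="burpee", reps=2, seed=9,
                          noise_sd=0.004, tempo_jitter=0.1)
        ta, gta = generate_trajectory(spec)
        tb, gtb = generate_trajectory(spec)
        assert gta == gtb
        for fa, fb in zip(ta.frames, tb.frames):
            for pa, pb in zip(fa.points, fb.points):
                assert pa.x == pb.x and pa.y == pb.y

    def test_ik_fidelity_on_every_parameter_eased_frame(self):
        # single-template recipes ease in angle space: every frame's
        # computed proxies are exact for some point between the keyframe
        # targets, and keyframe dwell frames hit the targets themselves
        for ex in ("squat", "deadlift", "shoulder_press", "pull_up"):
            traj, _ = generate_trajectory(MotionSpec(exercise=ex, reps=2,
                                                     seed=0))
            _, cycle = recipe(ex)
            keys = set(cycle[0].targets)
            bounds = {k: (min(kf.targets[k] for kf in cycle) - 1.0,
                          max(kf.targets[k] for kf in cycle) + 1.0)
                      for k in keys}
            for fr in traj.frames:
                av = angles_from_frame(fr)
                for k, (lo, hi) in bounds.items():
                    assert lo <= av.get(k) <= hi, (ex, fr.index, k)

    def test_box_jump_rises_during_takeoff(self):
        traj, gt = generate_trajectory(MotionSpec(exercise="box_jump",
                                                  reps=3, seed=0))
        stand_com = com_height(traj.frames[0])
        for a, b in gt.rep_windows:
            in_window = [com_height(f) for f in traj.frames[a:b + 1]]
            assert min(in_window) <= stand_com - 0.05  # image-up >= 0.05

    def test_tempo_jitter_changes_window_lengths(self):
        _, gt = generate_trajectory(MotionSpec(exercise="squat", reps=6,
                                               seed=4, tempo_jitter=0.25))
        lengths = {b - a for a, b in gt.rep_windows}
        assert len(lengths) > 1

    def test_counting_accuracy_nonincreasing_in_noise(self):
        levels = (0.0, 0.004, 0.012, 0.03)
        rates = []
        for sd in levels:
            exact = 0
            for seed in range(12):
                traj, _ = generate_trajectory(MotionSpec(
                    exercise="squat", reps=5, seed=seed, noise_sd=sd))
                exact += run(traj, builtin("squat"))[0] == 5
            rates.append(exact / 12)
        assert rates[0] == 1.0
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestInjectDropout:
    def test_empty_burst_list_is_identity(self, clean_squat):
        traj, _ = clean_squat
        assert inject_dropout(traj, []) == traj

    def test_burst_marks_expected_frames_absent(self, clean_squat):
        traj, _ = clean_squat
        out = inject_dropout(traj, [(10, 3)])
        empty = [i for i, f in enumerate(out.frames)
                 if not any(f.present_mask)]
        assert empty == [10, 11, 12]
        # purity: the original trajectory is untouched
        assert all(any(f.present_mask) for f in traj.frames)

    def test_subset_scope_drops_only_those_landmarks(self, clean_squat):
        traj, _ = clean_squat
        out = inject_dropout(traj, [(5, 2)], scope=[25, 26])
        f = out.frames[5]
        assert f.point(25) is None and f.point(26) is None
        assert f.point(23) is not None

    def test_out_of_range_burst_rejected(self, clean_squat):
        traj, _ = clean_squat
        with pytest.raises(ValueError):
            inject_dropout(traj, [(len(traj) - 1, 5)])
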