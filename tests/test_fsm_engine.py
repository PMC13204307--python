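"""FSM engine: phase matching, counting, persistence, trace statistics."""

import pytest

from mdlkit import builtin, run
from mdlkit.exercise_library import STRICT, ThresholdOverrides
from mdlkit.fsm_engine import (EngineConfig, false_transition_count,
                               phase_active, phase_coverage)
from mdlkit.pose_model import (LandmarkFrame, Trajectory, angles_from_frame)
from mdlkit.synthetic_motion import (MotionSpec, Posture, generate_trajectory,
                                     inject_dropout, pose_from_angles)

STRICT_CFG = EngineConfig(overrides=STRICT)


def _frame(targets, posture=Posture()):
    return pose_from_angles(targets, posture)


class TestPhaseActive:
    def test_squat_start_active_on_standing_angles(self):
        fr = _frame({"knee_angle": 170.0, "hip_angle": 165.0})
        av = angles_from_frame(fr)
        assert phase_active(av, fr, builtin("squat").phase(1), STRICT_CFG)

    def test_strict_boundary_is_exclusive(self):
        fr = _frame({"knee_angle": 160.0, "hip_angle": 165.0})
        av = angles_from_frame(fr)
        assert not phase_active(av, fr, builtin("squat").phase(1),
                                STRICT_CFG)

    def test_undefined_angle_makes_phase_inactive(self):
        fr = _frame({"knee_angle": 88.0, "hip_angle": 120.0})
        fr = fr.with_points([None if i in (25, 26) else p
                             for i, p in enumerate(fr.points)])
        av = angles_from_frame(fr)
        assert not phase_active(av, fr, builtin("squat").phase(2),
                                STRICT_CFG)


class TestCounting:
    def test_clean_five_rep_squat(self, clean_squat, squat_def):
        traj, gt = clean_squat
        count, events, trace = run(traj, squat_def)
        assert count == 5
        assert [e.count for e in events] == [1, 2, 3, 4, 5]
        # one event inside each ground-truth window
        for ev, (a, b) in zip(events, gt.rep_windows):
            assert a <= ev.frame_index <= b

    def test_constant_standing_pose_counts_zero(self, squat_def):
        fr = _frame({"knee_angle": 172.0, "hip_angle": 167.0})
        frames = tuple(LandmarkFrame(index=i, points=fr.points)
                       for i in range(100))
        count, events, _ = run(Trajectory(frames=frames, fps=30), squat_def)
        assert count == 0 and events == []

    def test_empty_trajectory_raises(self, squat_def):
        with pytest.raises(ValueError):
            run(Trajectory(frames=(), fps=30), squat_def)

    def test_concatenation_is_additive(self, squat_def):
        t1, _ = generate_trajectory(MotionSpec(exercise="squat", reps=3,
                                               seed=1))
        t2, _ = generate_trajectory(MotionSpec(exercise="squat", reps=3,
                                               seed=2))
        frames = list(t1.frames)
        frames += [LandmarkFrame(index=len(t1.frames) + i, points=f.points)
                   for i, f in enumerate(t2.frames)]
        count, _, _ = run(Trajectory(frames=tuple(frames), fps=30),
                          squat_def)
        assert count == 6

    def test_time_reversed_deadlift_counts_the_same(self):
        # the two-phase bent/extended cycle is symmetric under reversal
        traj, _ = generate_trajectory(MotionSpec(exercise="deadlift",
                                                 reps=4, seed=0))
        rev = Trajectory(frames=tuple(
            LandmarkFrame(index=i, points=f.points)
            for i, f in enumerate(reversed(traj.frames))), fps=traj.fps)
        d = builtin("deadlift")
        assert run(traj, d)[0] == run(rev, d)[0] == 4

    def test_determinism(self, clean_squat, squat_def):
        traj, _ = clean_squat
        r1 = run(traj, squat_def)
        r2 = run(traj, squat_def)
        assert r1[0] == r2[0] and r1[1] == r2[1]
        assert [t.effective_phase for t in r1[2]] == \
               [t.effective_phase for t in r2[2]]

    def test_rep_count_nondecreasing_and_events_ordered(self, clean_squat,
                                                        squat_def):
        traj, _ = clean_squat
        _, events, trace = run(traj, squat_def)
        idx = [e.frame_index for e in events]
        assert idx == sorted(idx) and len(set(idx)) == len(idx)

    def test_count_on_return_to_start_matches_planned_reps(self, squat_def):
        traj, _ = generate_trajectory(MotionSpec(exercise="squat", reps=5,
                                                 seed=0))
        count, _, _ = run(traj, squat_def,
                          EngineConfig(count_on="return_to_start"))
        assert count == 5


class TestIsometric:
    def test_plank_holds_counted_by_duration(self):
        traj, gt = generate_trajectory(MotionSpec(exercise="plank", reps=3,
                                                  seed=0))
        count, events, _ = run(traj, builtin("plank"))
        assert count == 3
        for ev, (a, b) in zip(events, gt.rep_windows):
            assert a <= ev.frame_index <= b

    def test_short_hold_not_counted(self):
        fr = _frame({"torso_angle": 170.0, "elbow_angle": 172.0},
                    Posture(template="horizontal"))
        frames = tuple(LandmarkFrame(index=i, points=fr.points)
                       for i in range(20))  # 0.67 s at 30 fps < 2 s hold
        count, _, _ = run(Trajectory(frames=frames, fps=30),
                          builtin("plank"))
        assert count == 0


class TestPersistence:
    @pytest.fixture()
    def burst_fixture(self, clean_squat, squat_def):
        traj, _ = clean_squat
        clean, events, _ = run(traj, squat_def)
        f2 = events[1].frame_index  # rep-2 final-phase entry
        return traj, clean, f2

    def test_bridging_matches_burst_length(self, burst_fixture, squat_def):
        traj, clean, f2 = burst_fixture
        for B in range(1, 7):
            broken = inject_dropout(traj, [(f2 - 1, B)])
            counts = []
            fts = []
            for N in range(0, 7):
                c, _, tr = run(broken, squat_def,
                               EngineConfig(persistence_n=N))
                counts.append(c)
                fts.append(false_transition_count(tr))
            # persistence long enough to bridge the burst recovers the
            # clean count; rep_count nondecreasing, false transitions
            # nonincreasing in N
            for N in range(0, 7):
                if N >= B:
                    assert counts[N] == clean
            assert counts == sorted(counts)
            assert fts == sorted(fts, reverse=True)

    def test_short_burst_harmless_with_default_persistence(
            self, burst_fixture, squat_def):
        traj, clean, f2 = burst_fixture
        broken = inject_dropout(traj, [(f2 - 1, 3)])
        assert run(broken, squat_def)[0] == clean

    def test_without_persistence_burst_interrupts(self, burst_fixture,
                                                  squat_def):
        traj, clean, f2 = burst_fixture
        broken = inject_dropout(traj, [(f2 - 1, 3)])
        c, _, tr = run(broken, squat_def, EngineConfig(persistence_n=0))
        assert c < clean
        assert false_transition_count(tr) >= 1

    def test_heavy_dropout_never_inflates_the_count(self, clean_squat,
                                                    squat_def):
        traj, _ = clean_squat
        clean, _, _ = run(traj, squat_def)
        bursts = [(k, 6) for k in range(10, len(traj) - 10, 25)]
        broken = inject_dropout(traj, bursts)
        for N in (0, 2, 4, 8):
            c, _, _ = run(broken, squat_def, EngineConfig(persistence_n=N))
            assert c <= clean


class TestTraceStatistics:
    def test_clean_run_full_coverage_no_false_transitions(
            self, clean_squat, squat_def):
        traj, _ = clean_squat
        _, events, trace = run(traj, squat_def)
        assert false_transition_count(trace) == 0
        assert phase_coverage(trace, events, squat_def.n_phases) == 1.0

    def test_coverage_against_external_windows(self, clean_squat,
                                               squat_def):
        traj, gt = clean_squat
        _, events, trace = run(traj, squat_def)
        windows = list(gt.rep_windows)
        assert phase_coverage(trace, events, squat_def.n_phases,
                              windows) == 1.0
        # a window where the engine saw nothing is counted as uncovered
        windows.append((0, 3))
        cov = phase_coverage(trace, events, squat_def.n_phases, windows)
        assert cov == pytest.approx(5 / 6)

    def test_zero_reps_coverage_is_not_applicable(self, squat_def):
        fr = _frame({"knee_angle": 172.0, "hip_angle": 167.0})
        frames = tuple(LandmarkFrame(index=i, points=fr.points)
                       for i in range(30))
        _, events, trace = run(Trajectory(frames=frames, fps=30), squat_def)
        assert phase_coverage(trace, events, 2) is None
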