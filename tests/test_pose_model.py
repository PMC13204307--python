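"""Angle proxies, positional helpers, and trajectory I/O."""

import math

import numpy as np
import pytest

from mdlkit import pose_model as pm
from mdlkit.pose_model import (DegenerateAngleError, LandmarkFrame,
                               LandmarkPoint, Trajectory, angles_from_frame,
                               com_height, compute_angle,
                               horizontal_alignment, is_above)


def P(x, y, z=None):
    return LandmarkPoint(x=x, y=y, z=z)


def atan2_angle(a, b, c):
    """Brute-force oracle: absolute difference of ray headings."""
    t1 = math.atan2(a.y - b.y, a.x - b.x)
    t2 = math.atan2(c.y - b.y, c.x - b.x)
    d = abs(t1 - t2) % (2 * math.pi)
    if d > math.pi:
        d = 2 * math.pi - d
    return math.degrees(d)


def frame_with(points: dict, default=(0.3, 0.3)):
    pts = [LandmarkPoint(*default)] * pm.N_LANDMARKS
    for i, p in points.items():
        pts[i] = p
    return LandmarkFrame(index=0, points=tuple(pts))


class TestComputeAngle:
    @pytest.mark.parametrize("a,b,c,expected,tol", [
        ((0, 1), (0, 0), (1, 0), 90.0, 1e-9),
        ((0, 0), (1, 0), (2, 0), 180.0, 1e-9),
        # identical rays: arccos loses a little precision near cos = 1
        ((2, 2), (1, 1), (2, 2), 0.0, 1e-5),
        ((1, 0), (0, 0), (math.cos(math.radians(60)),
                          math.sin(math.radians(60))), 60.0, 1e-9),
    ])
    def test_reference_angles(self, a, b, c, expected, tol):
        assert compute_angle(P(*a), P(*b), P(*c)) == pytest.approx(
            expected, abs=tol)

    def test_degenerate_rays_raise(self):
        with pytest.raises(DegenerateAngleError):
            compute_angle(P(1, 1), P(1, 1), P(2, 2))
        with pytest.raises(DegenerateAngleError):
            compute_angle(P(0, 0), P(1, 1), P(1, 1))

    def test_matches_atan2_oracle_on_random_triples(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(10_000):
            xs = rng.uniform(-2, 2, size=6)
            a, b, c = P(xs[0], xs[1]), P(xs[2], xs[3]), P(xs[4], xs[5])
            try:
                got = compute_angle(a, b, c)
            except DegenerateAngleError:
                continue
            worst = max(worst, abs(got - atan2_angle(a, b, c)))
        assert worst < 1e-6

    def test_outer_argument_symmetry_and_invariances(self):
        rng = np.random.default_rng(7)
        for _ in range(200)[0:200]:
            xs = rng.uniform(-1, 1, size=6)
            a, b, c = P(xs[0], xs[1]), P(xs[2], xs[3]), P(xs[4], xs[5])
            try:
                base = compute_angle(a, b, c)
            except DegenerateAngleError:
                continue
            assert compute_angle(c, b, a) == pytest.approx(base, abs=1e-9)
            dx, dy, s = rng.uniform(-3, 3), rng.uniform(-3, 3), rng.uniform(0.1, 5)
            moved = [P(s * (p.x + dx), s * (p.y + dy)) for p in (a, b, c)]
            assert compute_angle(*moved) == pytest.approx(base, abs=1e-9)

    def test_result_clamped_under_near_collinear_rounding(self):
        # nearly collinear points can push the cosine past +/-1 in floats
        a, b, c = P(0.1, 0.1), P(0.2, 0.2), P(0.30000000001, 0.3)
        assert 0.0 <= compute_angle(a, b, c) <= 180.0

    def test_uses_z_when_all_points_have_it(self):
        a, b, c = P(1, 0, 0), P(0, 0, 0), P(0, 0, 1)
        assert compute_angle(a, b, c) == pytest.approx(90.0, abs=1e-9)


class TestAnglesFromFrame:
    def test_vertical_collinear_leg_reads_180(self):
        fr = frame_with({23: P(0.5, 0.5), 25: P(0.5, 0.7), 27: P(0.5, 0.9)})
        assert angles_from_frame(fr).knee_angle == pytest.approx(180.0)

    def test_absence_undefines_only_dependent_angles(self):
        fr = frame_with({23: P(0.5, 0.5), 25: None, 27: P(0.5, 0.9),
                         11: P(0.45, 0.2), 13: P(0.45, 0.35),
                         15: P(0.5, 0.45)})
        av = angles_from_frame(fr)
        assert av.knee_angle is None
        assert av.elbow_angle is not None
        assert av.torso_angle is not None

    def test_mirror_consistency(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = [P(x, y) for x, y in rng.uniform(0.05, 0.95, size=(33, 2))]
            fr = LandmarkFrame(index=0, points=tuple(pts))
            a = angles_from_frame(fr, "as_printed")
            b = angles_from_frame(fr.mirrored(), "mirrored")
            for k, v in a.as_dict().items():
                assert b.get(k) == pytest.approx(v, abs=1e-9)

    def test_both_min_max_bracket_the_sides(self):
        rng = np.random.default_rng(1)
        pts = [P(x, y) for x, y in rng.uniform(0.05, 0.95, size=(33, 2))]
        fr = LandmarkFrame(index=0, points=tuple(pts))
        left = angles_from_frame(fr, "as_printed")
        right = angles_from_frame(fr, "mirrored")
        lo = angles_from_frame(fr, "both_min")
        hi = angles_from_frame(fr, "both_max")
        for k in left.as_dict():
            assert lo.get(k) == pytest.approx(min(left.get(k), right.get(k)))
            assert hi.get(k) == pytest.approx(max(left.get(k), right.get(k)))


class TestPositionalHelpers:
    def test_com_height_is_hip_midpoint(self):
        fr = frame_with({23: P(0.4, 0.6), 24: P(0.5, 0.8)})
        assert com_height(fr) == pytest.approx(0.7)
        assert com_height(frame_with({23: None})) is None

    @pytest.mark.parametrize("py,qy,margin,expected", [
        (0.2, 0.5, 0.0, True),
        (0.5, 0.5, 0.0, False),   # strict inequality
        (0.44, 0.5, 0.05, True),  # clears the margin by 0.01
        (0.46, 0.5, 0.05, False),
    ])
    def test_is_above(self, py, qy, margin, expected):
        assert is_above(P(0.5, py), P(0.5, qy), margin) is expected

    def test_is_above_undefined_on_absent(self):
        assert is_above(None, P(0, 0)) is None

    def test_horizontal_alignment_boundary_inclusive(self):
        fr = frame_with({11: P(0.3, 0.5), 23: P(0.7, 0.5)})
        assert horizontal_alignment(fr, max_tilt=0.0) is True
        fr = frame_with({11: P(0.5, 0.2), 23: P(0.5, 0.8)})
        assert horizontal_alignment(fr, max_tilt=20.0) is False
        # tilt exactly at the limit passes (<= is inclusive)
        dy = 0.4 * math.tan(math.radians(20.0))
        fr = frame_with({11: P(0.3, 0.5), 23: P(0.7, 0.5 + dy)})
        assert horizontal_alignment(fr, max_tilt=20.0 + 1e-9) is True


class TestTrajectoryIO:
    @pytest.fixture()
    def traj(self):
        rng = np.random.default_rng(5)
        frames = []
        for i in range(7):
            pts = [P(x, y) for x, y in rng.uniform(0, 1, size=(33, 2))]
            if i == 3:
                pts[10] = None  # a dropout
            frames.append(LandmarkFrame(index=i, timestamp=i / 25.0,
                                        points=tuple(pts)))
        return Trajectory(frames=tuple(frames), fps=25.0)

    def test_jsonl_round_trip(self, tmp_path, traj):
        p = tmp_path / "t.jsonl"
        pm.write_jsonl(traj, p)
        back = pm.read_jsonl(p)
        assert back.fps == traj.fps
        assert back == traj

    def test_csv_round_trip(self, tmp_path, traj):
        p = tmp_path / "t.csv"
        pm.write_csv(traj, p)
        back = pm.read_csv(p, fps=traj.fps)
        assert back == traj

    def test_invariants_enforced(self):
        fr = frame_with({})
        with pytest.raises(ValueError):
            Trajectory(frames=(fr, fr), fps=30)  # non-increasing indices
        with pytest.raises(ValueError):
            LandmarkFrame(index=0, points=(None,) * 5)
        with pytest.raises(ValueError):
            LandmarkPoint(x=float("nan"), y=0.0)


def test_sagittal_hip_variant_reads_shoulder_hip_knee():
    # a figure standing perfectly straight: the sagittal hip flexion angle
    # (shoulder-hip-knee) reads ~180 regardless of where the
    # contralateral hip sits
    from mdlkit.synthetic_motion import pose_from_angles
    fr = pose_from_angles({"knee_angle": 180.0, "torso_angle": 120.0})
    av = angles_from_frame(fr, sagittal_hip=True)
    assert av.hip_angle == pytest.approx(180.0, abs=6.0)
    assert angles_from_frame(fr).hip_angle != pytest.approx(180.0, abs=6.0)
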