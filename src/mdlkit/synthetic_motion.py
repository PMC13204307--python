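"""Synthetic 33-landmark trajectories with exact ground truth.

A planar (sagittal-view) stick figure with fixed segment lengths is posed
by *inverse kinematics from angle targets*: given target values for any of
the five angle proxies, :func:`pose_from_angles` places the 33 landmarks
so that each targeted triplet evaluates to its target almost exactly.
Exercises are described as short keyframe recipes (phase label, angle
targets, posture parameters); :func:`generate_trajectory` eases between
keyframes with half-cosine ramps, yielding smooth trajectories whose
per-frame intended phase and repetition windows are known exactly.
Gaussian landmark jitter and detection-dropout bursts emulate the failure
modes of monocular pose estimators at controllable severity.

Geometry notes (normalized image units, y down):

* Segment lengths: thigh = shank = 0.15, torso 0.22 (hip to shoulder),
  upper arm 0.10, forearm 0.085 — stylized anthropometric ratios.
* The contralateral hip (k24) and shoulder (k12) sit a fixed 0.03 from
  their partners; their *direction* is solved (law of sines) so that the
  printed ``hip_angle``, ``torso_angle`` and ``shoulder_angle`` triplets
  — which pass through these midline-adjacent points — evaluate exactly
  to their targets.  The remaining contralateral landmarks are translated
  copies of their partners by the same offset vector, which makes
  left-side and right-side angles identical by construction.
* Because ``hip_angle`` and ``torso_angle`` share the k24 placement, a
  single keyframe may target one of them but not both.

The generator emulates tempo variation, landmark noise and dropout; it
does not attempt photorealism, 3D depth, frontal views, or any specific
pose estimator's error distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .pose_model import (MIRROR_MAP, N_LANDMARKS, LandmarkFrame,
                         LandmarkPoint, Trajectory)

# segment lengths and offsets, normalized units
L_THIGH = 0.15
L_SHANK = 0.15
L_TORSO = 0.22
L_UA = 0.10     # upper arm
L_FA = 0.085    # forearm
D_HIP = 0.03    # k23 -> k24 offset
D_SHOULDER = 0.03  # k11 -> k12 offset
HEAD_NOSE = {"upright": 0.08, "horizontal": 0.10, "hang": 0.17}
HEAD_MOUTH = {"upright": 0.06, "horizontal": 0.08, "hang": 0.14}

TEMPLATES = ("upright", "horizontal", "hang")


class InfeasiblePoseError(ValueError):
    """Raised when the requested angle targets cannot be realized."""


@dataclass(frozen=True)
class Posture:
    """Template and free parameters of the stick figure for one keyframe."""

    template: str = "upright"
    anchor_x: float = 0.5
    ground_y: float = 0.88
    lean: float = 0.0           # torso tilt from vertical, deg (upright)
    arm_elevation: float = 0.0  # 0 = arms down, 1 = overhead (upright)
    com_shift: float = 0.0      # global upward shift (jumps), units
    face: float = 1.0           # +1 faces +x, -1 faces -x
    bar_y: float = 0.20         # bar height (hang template)

    def numeric_fields(self) -> dict[str, float]:
        return {"anchor_x": self.anchor_x, "ground_y": self.ground_y,
                "lean": self.lean, "arm_elevation": self.arm_elevation,
                "com_shift": self.com_shift, "bar_y": self.bar_y}


@dataclass(frozen=True)
class Keyframe:
    """One posture waypoint of a recipe.

    ``label`` is the intended phase index (or None for neutral postures);
    ``w_ease``/``w_dwell`` are relative frame weights for the transition
    into this keyframe and the stay at it.
    """

    label: Optional[int]
    targets: dict[str, float]
    posture: Posture
    w_ease: float = 1.0
    w_dwell: float = 0.5


@dataclass(frozen=True)
class MotionSpec:
    """What to generate: exercise, planned reps, tempo, degradation."""

    exercise: str
    reps: int = 5
    fps: float = 30.0
    frames_per_rep: int = 40
    tempo_jitter: float = 0.0       # fractional variation of rep duration
    noise_sd: float = 0.0           # landmark jitter, normalized units
    dropout: tuple[tuple[int, int], ...] = ()  # (start, length) bursts
    seed: int = 0
    view: str = "left_sagittal"     # or "right_sagittal"
    lead_in: int = 10
    lead_out: int = 10

    def __post_init__(self) -> None:
        if self.reps < 0:
            raise ValueError("reps must be >= 0")
        if self.frames_per_rep < 4:
            raise ValueError("frames_per_rep must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.tempo_jitter < 1:
            raise ValueError("tempo_jitter must be in [0, 1)")
        if self.view not in ("left_sagittal", "right_sagittal"):
            raise ValueError(
                f"view {self.view!r} not supported by the sagittal "
                f"generator (use left_sagittal or right_sagittal)")


@dataclass(frozen=True)
class GroundTruth:
    """Exact annotation of a generated trajectory."""

    rep_windows: tuple[tuple[int, int], ...]  # inclusive frame intervals
    labels: tuple[Optional[int], ...]         # per-frame intended phase

    def __post_init__(self) -> None:
        w = self.rep_windows
        if any(a > b for a, b in w):
            raise ValueError("malformed rep window")
        if any(w[i][1] >= w[i + 1][0] for i in range(len(w) - 1)):
            raise ValueError("rep windows must be ordered and disjoint")


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def _half_cosine(a: float, b: float, n: int) -> np.ndarray:
    """n-point eased ramp from a to b, inclusive of both endpoints."""
    t = np.linspace(0.0, 1.0, n)
    return a + (b - a) * 0.5 * (1.0 - np.cos(np.pi * t))


def angle_waveform(high: float, low: float, frames: int,
                   shape: str = "cosine", start: str = "high") -> np.ndarray:
    """One smooth angle cycle hitting both extremes exactly.

    ``start="high"`` gives high -> low -> high (e.g. a squat knee);
    ``start="low"`` the inverse (e.g. a deadlift torso).  The extreme
    opposite the start is attained exactly at mid-cycle.
    """
    if shape != "cosine":
        raise ValueError(f"unknown waveform shape {shape!r}")
    if not (0.0 <= low < high <= 180.0):
        raise ValueError("need 0 <= low < high <= 180")
    if frames < 4:
        raise ValueError("frames must be >= 4")
    a, b = (high, low) if start == "high" else (low, high)
    k = frames // 2 + 1
    down = _half_cosine(a, b, k)
    up = _half_cosine(b, a, frames - k + 1)
    return np.concatenate([down, up[1:]])


# ---------------------------------------------------------------------------
# inverse kinematics
# ---------------------------------------------------------------------------

def _rot(deg: float, v: tuple[float, float]) -> tuple[float, float]:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return (c * v[0] - s * v[1], s * v[0] + c * v[1])


def _unit(v: tuple[float, float]) -> tuple[float, float]:
    n = math.hypot(*v)
    return (v[0] / n, v[1] / n)


def _offset_direction(target: float, far: tuple[float, float],
                      near_len: float, far_len: float,
                      sign: float) -> tuple[float, float]:
    """Direction from a joint A to a nearby point B (|AB| = near_len) such
    that the angle *at B* between A and a far point C (A->C = ``far``,
    |AC| = far_len) equals ``target`` degrees (law of sines)."""
    s = near_len * math.sin(math.radians(target)) / far_len
    if abs(s) > 1.0:
        raise InfeasiblePoseError(f"offset angle {target} deg unreachable")
    c = math.degrees(math.asin(s))
    return _rot(sign * (180.0 - target - c), _unit(far))


def _fold(direction: tuple[float, float], interior: float,
          sign: float) -> tuple[float, float]:
    """Direction of the distal segment given the proximal direction and the
    interior angle at the joint between them."""
    return _rot(sign * (180.0 - interior), direction)


_ALLOWED_TARGETS = {"knee_angle", "hip_angle", "elbow_angle",
                    "shoulder_angle", "torso_angle"}


def pose_from_angles(targets: dict[str, float],
                     posture: Posture = Posture()) -> LandmarkFrame:
    """Render one stick-figure frame realizing the angle targets.

    Every targeted angle triplet evaluates back (via the angle proxies) to
    its target within well under a degree.  Untargeted angles take
    template defaults.  Deterministic: same inputs, same frame.

    Raises
    ------
    InfeasiblePoseError
        On targets outside [0, 180], on targeting ``hip_angle`` and
        ``torso_angle`` together (they share the contralateral-hip
        placement), or on geometrically unreachable combinations.
    """
    unknown = set(targets) - _ALLOWED_TARGETS
    if unknown:
        raise InfeasiblePoseError(f"unknown targets {sorted(unknown)}")
    if any(not 0.0 <= v <= 180.0 for v in targets.values()):
        raise InfeasiblePoseError("targets must lie in [0, 180]")
    if "hip_angle" in targets and "torso_angle" in targets:
        raise InfeasiblePoseError(
            "hip_angle and torso_angle cannot be targeted together: both "
            "are realized through the contralateral-hip placement")
    if posture.template not in TEMPLATES:
        raise InfeasiblePoseError(f"unknown template {posture.template!r}")

    f = posture.face
    knee_t = targets.get("knee_angle", 174.0)
    elbow_t = targets.get("elbow_angle", 170.0)
    P: dict[int, tuple[float, float]] = {}

    if posture.template == "upright":
        beta = math.radians((180.0 - knee_t) / 2.0)
        ankle = (posture.anchor_x, posture.ground_y)
        knee = (ankle[0] + L_SHANK * math.sin(beta) * f,
                ankle[1] - L_SHANK * math.cos(beta))
        hip = (knee[0] - L_THIGH * math.sin(beta) * f,
               knee[1] - L_THIGH * math.cos(beta))
        lr = math.radians(posture.lean)
        shoulder = (hip[0] + L_TORSO * math.sin(lr) * f,
                    hip[1] - L_TORSO * math.cos(lr))
        axis = _unit((shoulder[0] - hip[0], shoulder[1] - hip[1]))
        e = min(1.0, max(0.0, posture.arm_elevation))
        ua_dir = (math.sin(math.pi * e) * f, math.cos(math.pi * e))
        elbow = (shoulder[0] + L_UA * ua_dir[0], shoulder[1] + L_UA * ua_dir[1])
        fa_dir = _fold(ua_dir, elbow_t, -f)
        wrist = (elbow[0] + L_FA * fa_dir[0], elbow[1] + L_FA * fa_dir[1])
        P[27], P[25], P[23], P[11] = ankle, knee, hip, shoulder
        P[13], P[15] = elbow, wrist
    elif posture.template == "horizontal":
        # prone support: toes anchored, body a rigid line whose shoulder end
        # rides on the arms; wrists on the ground under the shoulders
        d_arm = math.sqrt(max(1e-12, L_UA ** 2 + L_FA ** 2
                              - 2 * L_UA * L_FA
                              * math.cos(math.radians(elbow_t))))
        body_len = 0.64
        toe = (posture.anchor_x + 0.32 * f, posture.ground_y)
        sh_y = posture.ground_y - d_arm
        dx = math.sqrt(max(0.0, body_len ** 2 - (toe[1] - sh_y) ** 2))
        shoulder = (toe[0] - dx * f, sh_y)
        bdir = _unit((toe[0] - shoulder[0], toe[1] - shoulder[1]))
        hip = (shoulder[0] + L_TORSO * bdir[0], shoulder[1] + L_TORSO * bdir[1])
        ankle = (toe[0] - 0.06 * bdir[0], toe[1] - 0.06 * bdir[1])
        knee = (ankle[0] - L_SHANK * bdir[0], ankle[1] - L_SHANK * bdir[1])
        axis = (-bdir[0], -bdir[1])
        wrist = (shoulder[0], posture.ground_y)
        a = (L_UA ** 2 - L_FA ** 2 + d_arm ** 2) / (2.0 * d_arm)
        h = math.sqrt(max(0.0, L_UA ** 2 - a ** 2))
        elbow = (shoulder[0] + h * f, shoulder[1] + a)
        P[27], P[25], P[23], P[11] = ankle, knee, hip, shoulder
        P[13], P[15] = elbow, wrist
    else:  # hang
        wrist = (posture.anchor_x, posture.bar_y)
        d_arm = math.sqrt(max(1e-12, L_UA ** 2 + L_FA ** 2
                              - 2 * L_UA * L_FA
                              * math.cos(math.radians(elbow_t))))
        shoulder = (wrist[0], wrist[1] + d_arm)
        a = (L_UA ** 2 - L_FA ** 2 + d_arm ** 2) / (2.0 * d_arm)
        h = math.sqrt(max(0.0, L_UA ** 2 - a ** 2))
        elbow = (shoulder[0] + h * f, shoulder[1] - a)
        hip = (shoulder[0], shoulder[1] + L_TORSO)
        axis = (0.0, -1.0)
        th = math.radians(5.0)
        thigh_dir = (math.sin(th) * f, math.cos(th))
        knee = (hip[0] + L_THIGH * thigh_dir[0], hip[1] + L_THIGH * thigh_dir[1])
        sh_dir = _fold(thigh_dir, knee_t, f)
        ankle = (knee[0] + L_SHANK * sh_dir[0], knee[1] + L_SHANK * sh_dir[1])
        P[27], P[25], P[23], P[11] = ankle, knee, hip, shoulder
        P[13], P[15] = elbow, wrist

    hip_pt, shoulder_pt = P[23], P[11]
    # contralateral hip: direction solved for torso_angle or hip_angle
    if "torso_angle" in targets:
        u = _unit((shoulder_pt[0] - hip_pt[0], shoulder_pt[1] - hip_pt[1]))
        delta = _rot(f * targets["torso_angle"], u)
    elif "hip_angle" in targets:
        thigh = (P[25][0] - hip_pt[0], P[25][1] - hip_pt[1])
        delta = _offset_direction(targets["hip_angle"], thigh, D_HIP,
                                  L_THIGH, f)
    else:
        u = _unit((shoulder_pt[0] - hip_pt[0], shoulder_pt[1] - hip_pt[1]))
        delta = _rot(f * 100.0, u)
    hip_off = (D_HIP * delta[0], D_HIP * delta[1])
    P[24] = (hip_pt[0] + hip_off[0], hip_pt[1] + hip_off[1])

    # contralateral shoulder likewise, for shoulder_angle
    ua = (P[13][0] - shoulder_pt[0], P[13][1] - shoulder_pt[1])
    if "shoulder_angle" in targets:
        delta_s = _offset_direction(targets["shoulder_angle"], ua,
                                    D_SHOULDER, L_UA, f)
    else:
        delta_s = _rot(f * 100.0, _unit(ua))
    sh_off = (D_SHOULDER * delta_s[0], D_SHOULDER * delta_s[1])
    P[12] = (shoulder_pt[0] + sh_off[0], shoulder_pt[1] + sh_off[1])

    # remaining right-side landmarks: exact translated copies, so both
    # sides evaluate to identical angles
    for left, off in ((25, hip_off), (27, hip_off),
                      (13, sh_off), (15, sh_off)):
        P[MIRROR_MAP[left]] = (P[left][0] + off[0], P[left][1] + off[1])

    # head, hands, feet dressing
    nose_d = HEAD_NOSE[posture.template]
    mouth_d = HEAD_MOUTH[posture.template]
    P[0] = (shoulder_pt[0] + nose_d * axis[0], shoulder_pt[1] + nose_d * axis[1])
    for i, dgn in ((9, mouth_d), (10, mouth_d)):
        side = 0.008 if i == 9 else -0.008
        P[i] = (shoulder_pt[0] + dgn * axis[0] + side,
                shoulder_pt[1] + dgn * axis[1])
    for i in (1, 2, 3):  # left eye cluster
        P[i] = (P[0][0] + 0.008 * (i - 1), P[0][1] - 0.012)
    for i in (4, 5, 6):  # right eye cluster
        P[i] = (P[0][0] - 0.008 * (i - 4), P[0][1] - 0.012)
    P[7] = (P[0][0] + 0.02, P[0][1] + 0.005)   # ears
    P[8] = (P[0][0] - 0.02, P[0][1] + 0.005)
    for base, wr in ((17, 15), (18, 16)):       # pinky/index/thumb
        for j, d in ((0, 0.015), (2, 0.02), (4, 0.012)):
            P[base + j] = (P[wr][0] + d * f, P[wr][1] + 0.004)
    for base, an in ((29, 27), (30, 28)):       # heels
        P[base] = (P[an][0] - 0.02 * f, P[an][1] + 0.01)
    for base, an in ((31, 27), (32, 28)):       # foot index
        P[base] = (P[an][0] + 0.04 * f, P[an][1] + 0.01)

    pts: list[Optional[LandmarkPoint]] = [None] * N_LANDMARKS
    for i in range(N_LANDMARKS):
        x, y = P[i]
        pts[i] = LandmarkPoint(x=x, y=y - posture.com_shift, visibility=1.0)
    return LandmarkFrame(index=0, points=tuple(pts))


# ---------------------------------------------------------------------------
# exercise recipes
# ---------------------------------------------------------------------------

def _kf(label, targets, posture, w_ease=1.0, w_dwell=0.5) -> Keyframe:
    return Keyframe(label=label, targets=dict(targets), posture=posture,
                    w_ease=w_ease, w_dwell=w_dwell)


_UP = Posture(template="upright")
_HOR = Posture(template="horizontal")
_HANG = Posture(template="hang")


def recipe(exercise: str) -> tuple[Keyframe, list[Keyframe]]:
    """Neutral keyframe and the per-repetition keyframe cycle for one
    built-in exercise."""
    if exercise == "squat":
        stand = {"knee_angle": 172.0, "hip_angle": 167.0}
        bottom = {"knee_angle": 88.0, "hip_angle": 122.0}
        up = replace(_UP, arm_elevation=0.1)
        dn = replace(_UP, arm_elevation=0.1, lean=12.0)
        return (_kf(None, stand, up),
                [_kf(1, stand, up), _kf(2, bottom, dn), _kf(1, stand, up)])
    if exercise == "deadlift":
        bent = {"torso_angle": 88.0, "elbow_angle": 172.0}
        tall = {"torso_angle": 170.0, "elbow_angle": 172.0}
        b = replace(_UP, lean=50.0, arm_elevation=0.3)
        t = replace(_UP, lean=3.0, arm_elevation=0.05)
        return (_kf(None, tall, t),
                [_kf(1, bent, b), _kf(2, tall, t)])
    if exercise == "lunge":
        tall = {"knee_angle": 172.0}
        low = {"knee_angle": 88.0}
        return (_kf(None, tall, _UP),
                [_kf(1, tall, _UP), _kf(2, low, _UP), _kf(3, tall, _UP)])
    if exercise == "shoulder_press":
        rack = {"elbow_angle": 63.0, "shoulder_angle": 63.0}
        over = {"elbow_angle": 170.0, "shoulder_angle": 170.0}
        lo = replace(_UP, arm_elevation=0.18)
        hi = replace(_UP, arm_elevation=1.0)
        return (_kf(None, rack, lo),
                [_kf(1, rack, lo), _kf(2, over, hi), _kf(3, rack, lo)])
    if exercise == "push_up":
        top = {"elbow_angle": 172.0, "torso_angle": 170.0}
        low = {"elbow_angle": 86.0, "torso_angle": 170.0}
        return (_kf(None, top, _HOR),
                [_kf(1, top, _HOR), _kf(2, low, _HOR), _kf(3, top, _HOR)])
    if exercise == "pull_up":
        hang = {"elbow_angle": 172.0, "torso_angle": 170.0}
        top = {"elbow_angle": 58.0, "torso_angle": 170.0}
        return (_kf(None, hang, _HANG),
                [_kf(1, hang, _HANG), _kf(2, top, _HANG),
                 _kf(3, hang, _HANG)])
    if exercise == "bent_over_row":
        out = {"torso_angle": 88.0, "elbow_angle": 172.0}
        pull = {"torso_angle": 88.0, "elbow_angle": 86.0}
        b = replace(_UP, lean=50.0, arm_elevation=0.3)
        return (_kf(None, out, b),
                [_kf(1, out, b), _kf(2, pull, b), _kf(3, out, b)])
    if exercise == "plank":
        hold = {"torso_angle": 170.0, "elbow_angle": 172.0}
        broken = {"torso_angle": 108.0, "elbow_angle": 172.0}
        return (_kf(None, broken, _HOR),
                [_kf(1, hold, _HOR, w_ease=0.6, w_dwell=4.0),
                 _kf(None, broken, _HOR, w_ease=0.6, w_dwell=1.2)])
    if exercise == "box_jump":
        stand = {"knee_angle": 172.0, "hip_angle": 167.0}
        crouch = {"knee_angle": 133.0, "hip_angle": 135.0}
        tuck = {"knee_angle": 88.0, "hip_angle": 88.0}
        up = _UP
        return (_kf(None, stand, up),
                [_kf(1, stand, up, w_ease=1.0, w_dwell=0.6),
                 _kf(2, crouch, replace(up, lean=10.0),
                     w_ease=1.0, w_dwell=0.0),
                 _kf(2, tuck, replace(up, lean=10.0, com_shift=0.20),
                     w_ease=0.45, w_dwell=0.5),
                 _kf(3, stand, up, w_ease=1.0, w_dwell=0.6)])
    if exercise == "thruster":
        rack = replace(_UP, arm_elevation=0.18)
        rack_dn = replace(_UP, arm_elevation=0.18, lean=12.0)
        over = replace(_UP, arm_elevation=1.0)
        stand_r = {"knee_angle": 172.0, "hip_angle": 167.0,
                   "elbow_angle": 63.0, "shoulder_angle": 63.0}
        bottom_r = {"knee_angle": 88.0, "hip_angle": 122.0,
                    "elbow_angle": 63.0, "shoulder_angle": 63.0}
        overhead = {"knee_angle": 172.0, "hip_angle": 167.0,
                    "elbow_angle": 170.0, "shoulder_angle": 170.0}
        return (_kf(None, stand_r, rack),
                [_kf(1, stand_r, rack), _kf(2, bottom_r, rack_dn),
                 _kf(3, stand_r, rack), _kf(4, overhead, over),
                 _kf(5, stand_r, rack)])
    if exercise == "overhead_squat":
        over = replace(_UP, arm_elevation=1.0)
        over_dn = replace(_UP, arm_elevation=1.0, lean=10.0)
        top = {"knee_angle": 172.0, "hip_angle": 167.0,
               "elbow_angle": 170.0, "shoulder_angle": 170.0}
        low = {"knee_angle": 88.0, "hip_angle": 122.0,
               "elbow_angle": 170.0, "shoulder_angle": 170.0}
        return (_kf(None, top, over),
                [_kf(1, top, over), _kf(2, low, over_dn), _kf(1, top, over)])
    if exercise == "burpee":
        stand = _kf(1, {"knee_angle": 172.0, "hip_angle": 167.0},
                    replace(_UP, arm_elevation=0.15), w_dwell=0.3)
        crouch = _kf(2, {"torso_angle": 88.0, "elbow_angle": 172.0,
                         "knee_angle": 122.0},
                     replace(_UP, lean=55.0, arm_elevation=0.45), w_dwell=0.3)
        plank = _kf(3, {"torso_angle": 170.0, "elbow_angle": 172.0},
                    _HOR, w_dwell=0.3)
        down = _kf(4, {"torso_angle": 170.0, "elbow_angle": 86.0},
                   _HOR, w_dwell=0.3)
        up_ = _kf(5, {"torso_angle": 170.0, "elbow_angle": 172.0},
                  _HOR, w_dwell=0.3)
        crouch2 = replace(crouch, label=6)
        jump = _kf(7, {"knee_angle": 172.0, "hip_angle": 167.0},
                   replace(_UP, arm_elevation=0.15, com_shift=0.14),
                   w_dwell=0.4)
        neutral = _kf(None, {"knee_angle": 172.0, "hip_angle": 167.0},
                      replace(_UP, arm_elevation=0.15))
        return (neutral, [stand, crouch, plank, down, up_, crouch2, jump])
    raise KeyError(f"no synthetic recipe for exercise {exercise!r}")


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _frame_params(kf_a: Keyframe, kf_b: Keyframe, s: float):
    """Interpolated (targets, posture) at eased progress s in [0, 1], when
    the pair is parameter-compatible."""
    targets = {k: kf_a.targets[k] + (kf_b.targets[k] - kf_a.targets[k]) * s
               for k in kf_b.targets}
    na, nb = kf_a.posture.numeric_fields(), kf_b.posture.numeric_fields()
    merged = {k: na[k] + (nb[k] - na[k]) * s for k in nb}
    posture = replace(kf_b.posture, **merged)
    return targets, posture


def _compatible(a: Keyframe, b: Keyframe) -> bool:
    return (a.posture.template == b.posture.template
            and set(a.targets) == set(b.targets))


def _blend_frames(fa: LandmarkFrame, fb: LandmarkFrame,
                  s: float) -> LandmarkFrame:
    pts = []
    for pa, pb in zip(fa.points, fb.points):
        pts.append(LandmarkPoint(
            x=pa.x + (pb.x - pa.x) * s, y=pa.y + (pb.y - pa.y) * s,
            visibility=1.0))
    return LandmarkFrame(index=0, points=tuple(pts))


def _render_segment(kf_a: Keyframe, kf_b: Keyframe, n_ease: int,
                    n_dwell: int) -> list[LandmarkFrame]:
    """Frames easing from keyframe a into keyframe b, plus b's dwell."""
    frames = []
    compatible = _compatible(kf_a, kf_b)
    if not compatible:
        fa = pose_from_angles(kf_a.targets, kf_a.posture)
        fb = pose_from_angles(kf_b.targets, kf_b.posture)
    for i in range(1, n_ease + 1):
        t = i / n_ease
        s = 0.5 * (1.0 - math.cos(math.pi * t))
        if compatible:
            targets, posture = _frame_params(kf_a, kf_b, s)
            frames.append(pose_from_angles(targets, posture))
        else:
            frames.append(_blend_frames(fa, fb, s))
    dwell_frame = frames[-1] if frames else pose_from_angles(
        kf_b.targets, kf_b.posture)
    frames.extend([dwell_frame] * n_dwell)
    return frames


def _alloc(weights: Sequence[float], total: int) -> list[int]:
    """Largest-remainder integer allocation; weight 0 stays 0, weight > 0
    gets at least 1 frame."""
    wsum = sum(weights)
    raw = [w / wsum * total for w in weights]
    out = [max(1, int(r)) if w > 0 else 0 for r, w in zip(raw, weights)]
    # trim or pad to match the total, never below 1 for positive weights
    diff = total - sum(out)
    order = sorted(range(len(out)), key=lambda i: raw[i] - out[i],
                   reverse=(diff > 0))
    j = 0
    while diff != 0 and j < 10 * len(out):
        i = order[j % len(out)]
        if diff > 0 and weights[i] > 0:
            out[i] += 1
            diff -= 1
        elif diff < 0 and out[i] > 1:
            out[i] -= 1
            diff += 1
        j += 1
    return out


def generate_trajectory(spec: MotionSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a landmark trajectory and its exact ground truth.

    Per-rep keyframe cycles are eased, concatenated, and book-ended by
    neutral lead-in/lead-out frames; Gaussian landmark noise and dropout
    bursts are applied last.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    neutral, cycle = recipe(spec.exercise)

    is_plank = spec.exercise == "plank"
    min_hold_frames = math.ceil(2.0 * spec.fps) + 8 if is_plank else 0

    frames: list[LandmarkFrame] = []
    labels: list[Optional[int]] = []
    windows: list[tuple[int, int]] = []

    neutral_frame = pose_from_angles(neutral.targets, neutral.posture)
    frames.extend([neutral_frame] * spec.lead_in)
    labels.extend([neutral.label] * spec.lead_in)

    prev_kf = neutral
    for _ in range(spec.reps):
        jitter = 1.0 + (rng.uniform(-spec.tempo_jitter, spec.tempo_jitter)
                        if spec.tempo_jitter > 0 else 0.0)
        rep_frames = max(4 * len(cycle), int(round(spec.frames_per_rep * jitter)))
        if is_plank:
            rep_frames = max(rep_frames, min_hold_frames + 16)
        weights = []
        for kf in cycle:
            weights.extend([kf.w_ease, kf.w_dwell])
        alloc = _alloc(weights, rep_frames)
        if is_plank:
            # guarantee the hold dwell covers the required duration
            hold_i = 1  # dwell slot of the first (holding) keyframe
            deficit = min_hold_frames - alloc[hold_i]
            if deficit > 0:
                alloc[hold_i] += deficit
        start = len(frames)
        for j, kf in enumerate(cycle):
            n_ease, n_dwell = alloc[2 * j], alloc[2 * j + 1]
            segment = _render_segment(prev_kf, kf, n_ease, n_dwell)
            frames.extend(segment)
            labels.extend([kf.label] * len(segment))
            prev_kf = kf
        windows.append((start, len(frames) - 1))

    tail = _render_segment(prev_kf, neutral,
                           max(1, spec.lead_out // 2),
                           spec.lead_out - max(1, spec.lead_out // 2))
    frames.extend(tail)
    labels.extend([neutral.label] * len(tail))

    out_frames: list[LandmarkFrame] = []
    for i, fr in enumerate(frames):
        pts = list(fr.points)
        if spec.noise_sd > 0:
            noise = rng.normal(0.0, spec.noise_sd, size=(N_LANDMARKS, 2))
            pts = [LandmarkPoint(x=p.x + noise[k, 0], y=p.y + noise[k, 1],
                                 visibility=p.visibility)
                   for k, p in enumerate(pts)]
        frame = LandmarkFrame(index=i, timestamp=i / spec.fps,
                              points=tuple(pts))
        if spec.view == "right_sagittal":
            frame = frame.mirrored()
        out_frames.append(frame)

    traj = Trajectory(frames=tuple(out_frames), fps=spec.fps)
    if spec.dropout:
        traj = inject_dropout(traj, list(spec.dropout))
    gt = GroundTruth(rep_windows=tuple(windows), labels=tuple(labels))
    return traj, gt


def inject_dropout(traj: Trajectory, bursts: Sequence[tuple[int, int]],
                   scope: str | Sequence[int] = "all") -> Trajectory:
    """Mark landmarks absent over each (start, length) burst.

    ``scope`` is ``"all"`` or a list of landmark indices.  Pure function:
    the input trajectory is untouched.
    """
    n = len(traj)
    for start, length in bursts:
        if start < 0 or length < 0 or start + length > n:
            raise ValueError(f"burst ({start}, {length}) out of range "
                             f"for {n} frames")
    indices = set(range(N_LANDMARKS)) if scope == "all" else set(scope)
    drop_frames: set[int] = set()
    for start, length in bursts:
        drop_frames.update(range(start, start + length))
    new_frames = []
    for pos, fr in enumerate(traj.frames):
        if pos in drop_frames:
            pts = [None if i in indices else p
                   for i, p in enumerate(fr.points)]
            new_frames.append(fr.with_points(pts))
        else:
            new_frames.append(fr)
    return Trajectory(frames=tuple(new_frames), fps=traj.fps)
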