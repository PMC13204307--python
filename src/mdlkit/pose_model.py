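"""Landmark trajectories and pose-derived angle proxies.

The package consumes per-frame body landmarks in the common 33-keypoint
monocular-estimator layout (``k0`` = nose, ``k11`` = left shoulder,
``k23`` = left hip, ...).  Coordinates are normalized image coordinates:
origin at the top-left, ``x`` to the right, ``y`` increasing *downward* —
so "above" means a *smaller* ``y``.

Angles are interior angles at a middle landmark, in degrees, and are
approximate kinematic proxies, not biomechanical joint measurements.
Five named proxies drive all exercise definitions::

    knee_angle     = theta(k23, k25, k27)   hip-knee-ankle
    hip_angle      = theta(k23, k24, k25)   left hip-right hip-left knee
    elbow_angle    = theta(k11, k13, k15)   shoulder-elbow-wrist
    shoulder_angle = theta(k11, k12, k13)   shoulder-shoulder-elbow
    torso_angle    = theta(k11, k23, k24)   shoulder-left hip-right hip

where ``theta(a, b, c)`` is the angle at ``b`` between rays ``b->a`` and
``b->c``.  Angles use (x, y) only unless all three constituent landmarks
carry a z coordinate.  A landmark may be absent (detection dropout); any
angle whose constituents are absent is *undefined* (``None``) rather than
an error, so temporal logic downstream decides how to cope.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, replace
from typing import Iterator, Optional, Sequence

import numpy as np

N_LANDMARKS = 33

#: Landmark indices used by the angle proxies and predicates.
NOSE = 0
MOUTH_LEFT, MOUTH_RIGHT = 9, 10
LEFT_SHOULDER, RIGHT_SHOULDER = 11, 12
LEFT_ELBOW, RIGHT_ELBOW = 13, 14
LEFT_WRIST, RIGHT_WRIST = 15, 16
LEFT_HIP, RIGHT_HIP = 23, 24
LEFT_KNEE, RIGHT_KNEE = 25, 26
LEFT_ANKLE, RIGHT_ANKLE = 27, 28

#: Contralateral partner of every sided landmark (midline points map to
#: themselves).  Fixed by the standard 33-point layout.
MIRROR_MAP: dict[int, int] = {0: 0}
for _l, _r in [(1, 4), (2, 5), (3, 6), (7, 8), (9, 10), (11, 12), (13, 14),
               (15, 16), (17, 18), (19, 20), (21, 22), (23, 24), (25, 26),
               (27, 28), (29, 30), (31, 32)]:
    MIRROR_MAP[_l] = _r
    MIRROR_MAP[_r] = _l

ANGLE_IDS = ("knee_angle", "hip_angle", "elbow_angle", "shoulder_angle",
             "torso_angle")

#: (a, b, c) landmark triplets, angle taken at b; left-side ("as printed")
#: convention.
ANGLE_TRIPLETS: dict[str, tuple[int, int, int]] = {
    "knee_angle": (LEFT_HIP, LEFT_KNEE, LEFT_ANKLE),
    "hip_angle": (LEFT_HIP, RIGHT_HIP, LEFT_KNEE),
    "elbow_angle": (LEFT_SHOULDER, LEFT_ELBOW, LEFT_WRIST),
    "shoulder_angle": (LEFT_SHOULDER, RIGHT_SHOULDER, LEFT_ELBOW),
    "torso_angle": (LEFT_SHOULDER, LEFT_HIP, RIGHT_HIP),
}

SIDE_MODES = ("as_printed", "mirrored", "both_min", "both_max")


class DegenerateAngleError(ValueError):
    """Raised when an angle is requested at a zero-length ray (a==b or c==b)."""


@dataclass(frozen=True)
class LandmarkPoint:
    """A single detected landmark in normalized image coordinates."""

    x: float
    y: float
    z: Optional[float] = None
    visibility: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("landmark coordinates must be finite")


@dataclass(frozen=True)
class LandmarkFrame:
    """One time point of the 33-keypoint pose.

    ``points`` has exactly 33 slots; an absent (dropped-out) landmark is
    ``None``.
    """

    index: int
    points: tuple[Optional[LandmarkPoint], ...]
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.points) != N_LANDMARKS:
            raise ValueError(f"expected {N_LANDMARKS} landmark slots, "
                             f"got {len(self.points)}")
        if self.index < 0:
            raise ValueError("frame index must be >= 0")

    @property
    def present_mask(self) -> tuple[bool, ...]:
        return tuple(p is not None for p in self.points)

    def point(self, i: int) -> Optional[LandmarkPoint]:
        return self.points[i]

    def with_points(self, points: Sequence[Optional[LandmarkPoint]]) -> "LandmarkFrame":
        return replace(self, points=tuple(points))

    def mirrored(self) -> "LandmarkFrame":
        """Swap every landmark with its contralateral partner."""
        pts: list[Optional[LandmarkPoint]] = [None] * N_LANDMARKS
        for i, p in enumerate(self.points):
            pts[MIRROR_MAP[i]] = p
        return self.with_points(pts)


@dataclass(frozen=True)
class Trajectory:
    """An ordered sequence of landmark frames sampled at ``fps`` Hz."""

    frames: tuple[LandmarkFrame, ...]
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        idx = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[LandmarkFrame]:
        return iter(self.frames)


@dataclass(frozen=True)
class AngleVector:
    """Named angle proxies (degrees) for one frame; ``None`` = undefined."""

    knee_angle: Optional[float] = None
    hip_angle: Optional[float] = None
    elbow_angle: Optional[float] = None
    shoulder_angle: Optional[float] = None
    torso_angle: Optional[float] = None
    side: str = "as_printed"

    def get(self, angle_id: str) -> Optional[float]:
        return getattr(self, angle_id)

    def as_dict(self) -> dict[str, Optional[float]]:
        return {a: getattr(self, a) for a in ANGLE_IDS}


def _vec(frm: LandmarkPoint, to: LandmarkPoint, use_z: bool) -> np.ndarray:
    if use_z:
        return np.array([to.x - frm.x, to.y - frm.y, to.z - frm.z])
    return np.array([to.x - frm.x, to.y - frm.y])


def compute_angle(a: LandmarkPoint, b: LandmarkPoint, c: LandmarkPoint) -> float:
    """Interior angle at ``b`` between rays ``b->a`` and ``b->c``, degrees.

    Uses (x, y) always; z enters only when all three points carry it.
    The cosine is clipped to [-1, 1], so the result is always in [0, 180].

    Raises
    ------
    DegenerateAngleError
        If ``a == b`` or ``c == b`` (a zero-length ray), signalling
        unusable landmarks; callers treat the angle as undefined.
    """
    use_z = all(p.z is not None for p in (a, b, c))
    u = _vec(b, a, use_z)
    v = _vec(b, c, use_z)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateAngleError("zero-length ray in angle triplet")
    cosang = float(np.dot(u, v) / (nu * nv))
    cosang = min(1.0, max(-1.0, cosang))
    return math.degrees(math.acos(cosang))


def _triplet_angle(frame: LandmarkFrame, ia: int, ib: int, ic: int) -> Optional[float]:
    a, b, c = frame.point(ia), frame.point(ib), frame.point(ic)
    if a is None or b is None or c is None:
        return None
    try:
        return compute_angle(a, b, c)
    except DegenerateAngleError:
        return None


#: Alternate sagittal hip-flexion triplet (shoulder-hip-knee), selectable
#: in place of the canonical hip triplet which pivots at the
#: contralateral hip.
SAGITTAL_HIP_TRIPLET = (LEFT_SHOULDER, LEFT_HIP, LEFT_KNEE)


def angles_from_frame(frame: LandmarkFrame, side_mode: str = "as_printed",
                      sagittal_hip: bool = False) -> AngleVector:
    """Compute the five angle proxies for one frame.

    ``side_mode``:

    * ``as_printed`` — the left-side triplets above.
    * ``mirrored``   — every index swapped for its contralateral partner.
    * ``both_min`` / ``both_max`` — elementwise min/max of the two sides
      (an undefined side is ignored; both undefined stays undefined).

    ``sagittal_hip`` replaces the canonical hip triplet with the
    shoulder-hip-knee flexion angle.
    """
    if side_mode not in SIDE_MODES:
        raise ValueError(f"unknown side_mode {side_mode!r}")
    triplets = dict(ANGLE_TRIPLETS)
    if sagittal_hip:
        triplets["hip_angle"] = SAGITTAL_HIP_TRIPLET

    def one_side(mirror: bool) -> dict[str, Optional[float]]:
        out = {}
        for name, (ia, ib, ic) in triplets.items():
            if mirror:
                ia, ib, ic = MIRROR_MAP[ia], MIRROR_MAP[ib], MIRROR_MAP[ic]
            out[name] = _triplet_angle(frame, ia, ib, ic)
        return out

    if side_mode == "as_printed":
        vals = one_side(False)
    elif side_mode == "mirrored":
        vals = one_side(True)
    else:
        left = one_side(False)
        right = one_side(True)
        combine = min if side_mode == "both_min" else max
        vals = {}
        for name in ANGLE_IDS:
            pair = [v for v in (left[name], right[name]) if v is not None]
            vals[name] = combine(pair) if pair else None
    return AngleVector(side=side_mode, **vals)


def both_sides_angle(frame: LandmarkFrame, angle_id: str) -> tuple[Optional[float], Optional[float]]:
    """(as-printed, mirrored) values of one angle proxy."""
    ia, ib, ic = ANGLE_TRIPLETS[angle_id]
    left = _triplet_angle(frame, ia, ib, ic)
    right = _triplet_angle(frame, MIRROR_MAP[ia], MIRROR_MAP[ib], MIRROR_MAP[ic])
    return left, right


def com_height(frame: LandmarkFrame) -> Optional[float]:
    """Hip-midpoint ordinate, a proxy for center-of-mass height.

    Smaller values are higher in the image.  Undefined (``None``) when
    either hip landmark is absent.
    """
    lh, rh = frame.point(LEFT_HIP), frame.point(RIGHT_HIP)
    if lh is None or rh is None:
        return None
    return 0.5 * (lh.y + rh.y)


def is_above(p: Optional[LandmarkPoint], q: Optional[LandmarkPoint],
             margin: float = 0.0) -> Optional[bool]:
    """True iff ``p`` is strictly above ``q`` by at least ``margin``.

    Image y grows downward, so above means ``p.y < q.y - margin``.
    Undefined (``None``) when either point is absent.
    """
    if p is None or q is None:
        return None
    return p.y < q.y - margin


def horizontal_alignment(frame: LandmarkFrame, max_tilt: float = 20.0) -> Optional[bool]:
    """Whether the shoulder->hip segment lies within ``max_tilt`` degrees
    of the image horizontal (inclusive), on the first side with both
    landmarks present (left preferred).  Undefined when no side has both.
    """
    for sh_i, hip_i in ((LEFT_SHOULDER, LEFT_HIP), (RIGHT_SHOULDER, RIGHT_HIP)):
        sh, hip = frame.point(sh_i), frame.point(hip_i)
        if sh is not None and hip is not None:
            dx = hip.x - sh.x
            dy = hip.y - sh.y
            if dx == 0.0 and dy == 0.0:
                return None
            tilt = abs(math.degrees(math.atan2(dy, dx)))
            tilt = min(tilt, 180.0 - tilt)  # direction-agnostic
            return tilt <= max_tilt
    return None


# ---------------------------------------------------------------------------
# Trajectory file formats
# ---------------------------------------------------------------------------
# JSONL dialect: first line is a header object {"format": "mdl-landmarks",
# "fps": <Hz>}; every following line is one frame:
#   {"index": i, "timestamp": t|null, "points": [[x, y, z|null, v|null]|null]*33}
# CSV dialect (wide): columns index, timestamp, then k{i}_x, k{i}_y, k{i}_z,
# k{i}_v for i in 0..32; absent landmarks leave all four fields empty.

JSONL_FORMAT_NAME = "mdl-landmarks"


def _point_to_list(p: Optional[LandmarkPoint]):
    if p is None:
        return None
    return [p.x, p.y, p.z, p.visibility]


def _point_from_list(v) -> Optional[LandmarkPoint]:
    if v is None:
        return None
    x, y, z, vis = v
    return LandmarkPoint(x=x, y=y, z=z, visibility=vis)


def write_jsonl(traj: Trajectory, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"format": JSONL_FORMAT_NAME, "fps": traj.fps}) + "\n")
        for f in traj.frames:
            rec = {"index": f.index, "timestamp": f.timestamp,
                   "points": [_point_to_list(p) for p in f.points]}
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path) -> Trajectory:
    with open(path, "r", encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        if header.get("format") != JSONL_FORMAT_NAME:
            raise ValueError(f"not a {JSONL_FORMAT_NAME} file: {path}")
        frames = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            frames.append(LandmarkFrame(
                index=rec["index"], timestamp=rec.get("timestamp"),
                points=tuple(_point_from_list(v) for v in rec["points"])))
    return Trajectory(frames=tuple(frames), fps=float(header["fps"]))


def _csv_header() -> list[str]:
    cols = ["index", "timestamp"]
    for i in range(N_LANDMARKS):
        cols += [f"k{i}_x", f"k{i}_y", f"k{i}_z", f"k{i}_v"]
    return cols


def write_csv(traj: Trajectory, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_csv_header())
        for f in traj.frames:
            row: list = [f.index,
                         "" if f.timestamp is None else repr(float(f.timestamp))]
            for p in f.points:
                if p is None:
                    row += ["", "", "", ""]
                else:
                    row += [repr(float(p.x)), repr(float(p.y)),
                            "" if p.z is None else repr(float(p.z)),
                            "" if p.visibility is None
                            else repr(float(p.visibility))]
            w.writerow(row)


def read_csv(path, fps: float = 30.0) -> Trajectory:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header[:2] != ["index", "timestamp"]:
            raise ValueError(f"not a wide landmark CSV: {path}")
        frames = []
        for row in r:
            if not row:
                continue
            pts: list[Optional[LandmarkPoint]] = []
            for i in range(N_LANDMARKS):
                base = 2 + 4 * i
                xs, ys, zs, vs = row[base:base + 4]
                if xs == "":
                    pts.append(None)
                else:
                    pts.append(LandmarkPoint(
                        x=float(xs), y=float(ys),
                        z=None if zs == "" else float(zs),
                        visibility=None if vs == "" else float(vs)))
            ts = None if row[1] == "" else float(row[1])
            frames.append(LandmarkFrame(index=int(row[0]), timestamp=ts,
                                        points=tuple(pts)))
    return Trajectory(frames=tuple(frames), fps=fps)


def read_trajectory(path, fps: float = 30.0) -> Trajectory:
    """Dispatch on extension: ``.jsonl`` or ``.csv``."""
    s = str(path)
    if s.endswith(".jsonl"):
        return read_jsonl(path)
    if s.endswith(".csv"):
        return read_csv(path, fps=fps)
    raise ValueError(f"unrecognized trajectory format: {path}")
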