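"""Finite-state-machine engine: phase detection and repetition counting.

Each exercise definition runs as a strict-cycle FSM over a landmark
trajectory.  Per frame, the engine computes the angle proxies, then:

1. If the *expected* phase (the next one in the cycle) is active, the
   machine advances to it.  When both the current and the expected phase
   are simultaneously active (overlapping relaxed thresholds), the
   expected phase wins — a forward-progress tie-break.
2. Otherwise, if the current phase is still active, the machine stays put.
3. Otherwise *adaptive phase persistence* retains the last valid phase for
   up to N frames (default 4, the midpoint of the typical 3-5 range),
   bridging transient landmark dropouts and noisy detections.  When the
   window is exhausted the machine drops to ``None`` and the cycle
   expectation resets; a drop while a cycle was in progress is logged as a
   *false transition*.

A repetition is counted at the frame where the *final* phase of the cycle
becomes active after every prior phase was visited in order (the default),
or — behind the ``count_on="return_to_start"`` switch — when phase 1
reactivates after a full traversal.  Only current-or-expected phases are
ever matched, so phases cannot be skipped.

Isometric definitions (plank) count by time instead: one repetition when
the single phase has been held continuously for ``min_hold`` seconds; a
new hold requires the phase to deactivate for at least N frames first.

Positional predicates that need temporal context (``vertical_rise`` /
``vertical_return``) are measured against the hip-midpoint height recorded
while the machine was last in phase 1 (the standing baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import pose_model
from .exercise_library import ThresholdOverrides, apply_overrides
from .mdl_lang import ExerciseDef, Phase, PositionalPredicate
from .pose_model import (AngleVector, LandmarkFrame, Trajectory,
                         angles_from_frame, both_sides_angle, com_height,
                         horizontal_alignment, is_above)


@dataclass(frozen=True)
class EngineConfig:
    """Engine tuning knobs.

    persistence_n : int
        Frames the last valid phase is retained when nothing matches
        (0 disables persistence; valid 0-30).
    overrides : ThresholdOverrides
        Hierarchical threshold configuration (default: 30 deg global
        tolerance).
    side_mode : str
        Which body side the angle triplets are taken from.
    count_on : str
        ``"final_phase"`` (default) or ``"return_to_start"``.
    min_hold : float or None
        Override of the definition's hold duration, seconds (isometric).
    """

    persistence_n: int = 4
    overrides: ThresholdOverrides = field(default_factory=ThresholdOverrides)
    side_mode: str = "as_printed"
    count_on: str = "final_phase"
    min_hold: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.persistence_n <= 30:
            raise ValueError("persistence_n must be in [0, 30]")
        if self.count_on not in ("final_phase", "return_to_start"):
            raise ValueError(f"unknown count_on {self.count_on!r}")
        if self.side_mode not in pose_model.SIDE_MODES:
            raise ValueError(f"unknown side_mode {self.side_mode!r}")


@dataclass(frozen=True)
class RepEvent:
    """A counted repetition (or completed hold)."""

    frame_index: int
    exercise: str
    count: int


@dataclass
class TraceRecord:
    """Per-frame engine record: what matched and what was in effect."""

    frame_index: int
    matched_phase: Optional[int]
    effective_phase: Optional[int]
    angles: AngleVector
    events: tuple[str, ...] = ()


@dataclass
class EngineState:
    """Mutable FSM runtime state."""

    current_phase: Optional[int] = None
    expected_phase: int = 1
    persistence_counter: int = 0
    rep_count: int = 0
    hold_frames: int = 0
    hold_armed: bool = True
    inactive_streak: int = 0
    visited_in_cycle: int = 0  # phases reached this cycle, in order
    last_matched: Optional[int] = None
    baseline_com: Optional[float] = None
    events: list[RepEvent] = field(default_factory=list)
    trace: list[TraceRecord] = field(default_factory=list)


def evaluate_predicate(pred: PositionalPredicate, frame: LandmarkFrame,
                       baseline_com: Optional[float]) -> Optional[bool]:
    """Evaluate one positional predicate on a frame.

    Returns ``None`` (undefined) when required landmarks are absent or,
    for the vertical predicates, when no phase-1 baseline exists yet.
    """
    pm = pose_model
    if pred.kind == "hands_and_elbows_above_head":
        head = frame.point(pm.NOSE)
        if head is None:
            return None
        parts = [frame.point(i) for i in (pm.LEFT_WRIST, pm.RIGHT_WRIST,
                                          pm.LEFT_ELBOW, pm.RIGHT_ELBOW)]
        present = [p for p in parts if p is not None]
        if not present:
            return None
        return all(is_above(p, head, pred.parameter) for p in present)
    if pred.kind == "chin_above_hands":
        mouth = [frame.point(i) for i in (pm.MOUTH_LEFT, pm.MOUTH_RIGHT)]
        mouth = [p for p in mouth if p is not None]
        wrists = [frame.point(i) for i in (pm.LEFT_WRIST, pm.RIGHT_WRIST)]
        wrists = [p for p in wrists if p is not None]
        if not mouth or not wrists:
            return None
        chin_y = sum(p.y for p in mouth) / len(mouth)
        hand_y = min(p.y for p in wrists)  # the higher hand (bar height)
        return chin_y < hand_y - pred.parameter
    if pred.kind == "horizontal_alignment":
        return horizontal_alignment(frame, max_tilt=pred.parameter)
    if pred.kind in ("vertical_rise", "vertical_return"):
        com = com_height(frame)
        if com is None or baseline_com is None:
            return None
        if pred.kind == "vertical_rise":
            # image y grows downward: risen means com decreased
            return com <= baseline_com - pred.parameter
        return abs(com - baseline_com) <= pred.parameter
    raise ValueError(f"unknown predicate {pred.kind!r}")


def _condition_holds(cond, angles: AngleVector, frame: LandmarkFrame,
                     side_mode: str) -> bool:
    if cond.both_sides:
        left, right = both_sides_angle(frame, cond.angle_id)
        return cond.holds(left) and cond.holds(right)
    return cond.holds(angles.get(cond.angle_id))


def phase_active(angles: AngleVector, frame: LandmarkFrame, phase: Phase,
                 cfg: EngineConfig,
                 baseline_com: Optional[float] = None) -> bool:
    """Whether every condition and predicate of an (effective) phase holds.

    Undefined angles or predicates make the phase inactive, never an error;
    the persistence logic decides how to cope with dropouts.
    """
    for c in phase.conditions:
        if not _condition_holds(c, angles, frame, cfg.side_mode):
            return False
    for p in phase.predicates:
        if evaluate_predicate(p, frame, baseline_com) is not True:
            return False
    return True


def init_state() -> EngineState:
    return EngineState()


def _count_rep(state: EngineState, frame: LandmarkFrame, name: str) -> None:
    state.rep_count += 1
    state.events.append(RepEvent(frame_index=frame.index, exercise=name,
                                 count=state.rep_count))


def step(state: EngineState, frame: LandmarkFrame, exercise: ExerciseDef,
         cfg: EngineConfig, fps: float = 30.0,
         effective: Optional[ExerciseDef] = None) -> EngineState:
    """Advance the FSM by one frame (mutates and returns ``state``).

    ``effective`` is the definition with overrides applied; callers doing
    whole-trajectory runs precompute it once.
    """
    if effective is None:
        effective = apply_overrides(exercise, cfg.overrides)
    angles = angles_from_frame(frame, side_mode=cfg.side_mode)
    events: list[str] = []

    if exercise.mode == "isometric":
        _step_isometric(state, frame, exercise, effective, cfg, fps, angles,
                        events)
    else:
        _step_cyclic(state, frame, exercise, effective, cfg, angles, events)

    # phase-1 baseline for the vertical predicates
    if state.current_phase == 1:
        com = com_height(frame)
        if com is not None:
            state.baseline_com = com

    state.trace.append(TraceRecord(
        frame_index=frame.index,
        matched_phase=state.last_matched,
        effective_phase=state.current_phase,
        angles=angles, events=tuple(events)))
    return state


def _step_cyclic(state: EngineState, frame: LandmarkFrame,
                 exercise: ExerciseDef, effective: ExerciseDef,
                 cfg: EngineConfig, angles: AngleVector,
                 events: list[str]) -> None:
    n = effective.n_phases
    expected = effective.phase(state.expected_phase)
    exp_active = phase_active(angles, frame, expected, cfg,
                              state.baseline_com)
    cur_active = False
    if not exp_active and state.current_phase is not None:
        cur = effective.phase(state.current_phase)
        cur_active = phase_active(angles, frame, cur, cfg, state.baseline_com)

    if exp_active:
        advancing_from = state.current_phase
        state.current_phase = state.expected_phase
        state.persistence_counter = cfg.persistence_n
        state.visited_in_cycle += 1
        events.append(f"enter_phase_{state.current_phase}")
        if cfg.count_on == "final_phase":
            if state.current_phase == n and state.visited_in_cycle >= n:
                _count_rep(state, frame, exercise.name)
                events.append("rep")
                state.expected_phase = 1
                state.visited_in_cycle = 0
            else:
                state.expected_phase = state.current_phase % n + 1
        else:  # return_to_start
            if state.current_phase == 1 and state.visited_in_cycle >= n + 1:
                _count_rep(state, frame, exercise.name)
                events.append("rep")
                state.visited_in_cycle = 1  # phase 1 starts the next cycle
            state.expected_phase = state.current_phase % n + 1
        state.last_matched = state.current_phase
    elif cur_active:
        state.persistence_counter = cfg.persistence_n
        state.last_matched = state.current_phase
    else:
        state.last_matched = None
        if state.current_phase is not None:
            if state.persistence_counter > 0:
                state.persistence_counter -= 1
                events.append("persistence")
            else:
                if state.expected_phase > 1:
                    events.append("false_transition")
                events.append("to_none")
                state.current_phase = None
                state.expected_phase = 1
                state.visited_in_cycle = 0


def _step_isometric(state: EngineState, frame: LandmarkFrame,
                    exercise: ExerciseDef, effective: ExerciseDef,
                    cfg: EngineConfig, fps: float, angles: AngleVector,
                    events: list[str]) -> None:
    phase = effective.phase(1)
    active = phase_active(angles, frame, phase, cfg, state.baseline_com)
    min_hold = cfg.min_hold if cfg.min_hold is not None else \
        (exercise.min_hold if exercise.min_hold is not None else 2.0)
    need = max(1, math.ceil(min_hold * fps))

    if active:
        state.current_phase = 1
        state.persistence_counter = cfg.persistence_n
        state.inactive_streak = 0
        state.hold_frames += 1
        state.last_matched = 1
        events.append("hold")
        if state.hold_armed and state.hold_frames >= need:
            _count_rep(state, frame, exercise.name)
            events.append("rep")
            state.hold_armed = False
    else:
        state.last_matched = None
        if state.current_phase is not None and state.persistence_counter > 0:
            state.persistence_counter -= 1
            state.hold_frames += 1  # persistence bridges the hold
            events.append("persistence")
        else:
            if state.current_phase is not None:
                events.append("to_none")
            state.current_phase = None
            state.hold_frames = 0
            state.inactive_streak += 1
            # re-arm after a sustained break
            if not state.hold_armed and \
               state.inactive_streak >= max(1, cfg.persistence_n):
                state.hold_armed = True


def run(trajectory: Trajectory, exercise: ExerciseDef,
        cfg: Optional[EngineConfig] = None
        ) -> tuple[int, list[RepEvent], list[TraceRecord]]:
    """Run a definition over a whole trajectory.

    Returns ``(rep_count, events, trace)``.  Deterministic for fixed
    inputs.  Raises ``ValueError`` on an empty trajectory.
    """
    if cfg is None:
        cfg = EngineConfig()
    if len(trajectory) == 0:
        raise ValueError("cannot run on an empty trajectory")
    effective = apply_overrides(exercise, cfg.overrides)
    state = init_state()
    for frame in trajectory:
        step(state, frame, exercise, cfg, fps=trajectory.fps,
             effective=effective)
    return state.rep_count, state.events, state.trace


def false_transition_count(trace: Sequence[TraceRecord]) -> int:
    """Drops from a valid phase to ``None`` while a cycle was in progress."""
    return sum(1 for r in trace if "false_transition" in r.events)


def phase_coverage(trace: Sequence[TraceRecord], events: Sequence[RepEvent],
                   n_phases: int,
                   windows: Optional[Sequence[tuple[int, int]]] = None
                   ) -> Optional[float]:
    """Fraction of repetitions whose trace shows every phase in order.

    Without external ground truth this is measured over engine-counted
    reps and equals 1.0 by construction (the engine only counts ordered
    traversals) — a consistency check.  With ground-truth ``windows``
    (inclusive frame intervals), it is the fraction of windows containing
    a complete in-order phase traversal.  ``None`` when there is nothing
    to measure.
    """
    def complete(records: Sequence[TraceRecord]) -> bool:
        want = 1
        for r in records:
            for ev in r.events:
                if ev == f"enter_phase_{want}":
                    want += 1
                    if want > n_phases:
                        return True
        return False

    if windows is None:
        if not events:
            return None
        # split the trace at rep events; each rep's records must traverse
        covered = 0
        start = 0
        by_index = {r.frame_index: i for i, r in enumerate(trace)}
        for ev in events:
            end = by_index[ev.frame_index]
            if complete(trace[start:end + 1]):
                covered += 1
            start = end + 1
        return covered / len(events)
    if not windows:
        return None

    def traversed(records: Sequence[TraceRecord]) -> bool:
        # the effective-phase sequence contains 1..n as a subsequence
        want = 1
        for r in records:
            if r.effective_phase == want:
                want += 1
                if want > n_phases:
                    return True
        return False

    covered = 0
    for (a, b) in windows:
        records = [r for r in trace if a <= r.frame_index <= b]
        if traversed(records):
            covered += 1
    return covered / len(windows)


def trace_to_rows(trace: Sequence[TraceRecord]) -> list[dict]:
    """Flatten a trace for tabular export (one dict per frame)."""
    rows = []
    for r in trace:
        row = {"frame": r.frame_index, "matched_phase": r.matched_phase,
               "effective_phase": r.effective_phase,
               "events": ";".join(r.events)}
        row.update(r.angles.as_dict())
        rows.append(row)
    return rows
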