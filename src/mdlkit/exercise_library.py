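"""Built-in exercise definitions and the hierarchical threshold system.

Twelve functional-training exercises ship with the package: nine
primitives (squat, deadlift, lunge, shoulder press, push-up, pull-up,
bent-over row, plank, box jump) and three compounds built from them
(thruster, overhead squat, burpee).  The primitive definitions carry the
default angle thresholds of the reference definitions; all thresholds are
user-adjustable through :class:`ThresholdOverrides`.

The override system is hierarchical: a global tolerance (default 30
degrees) applies everywhere, a per-exercise tolerance overrides it, and a
per-condition replacement threshold overrides both.  Tolerance *relaxes*
conditions toward satisfiability — ``> t`` becomes ``> t - tau`` and
``< t`` becomes ``< t + tau`` — absorbing pose-estimation uncertainty and
inter-individual mobility differences.  Positional predicate parameters
are never relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .mdl_lang import ExerciseDef, MDLSemanticError, parse_mdl

#: Default global threshold tolerance, degrees.
DEFAULT_TOLERANCE = 30.0

BUILTIN_NAMES = ("squat", "deadlift", "lunge", "shoulder_press", "push_up",
                 "pull_up", "bent_over_row", "plank", "box_jump",
                 "thruster", "overhead_squat", "burpee")

PRIMITIVE_NAMES = BUILTIN_NAMES[:9]
COMPOUND_NAMES = BUILTIN_NAMES[9:]

# Primitive definitions, in MDL itself.  Thresholds follow the reference
# defaults (squat per the canonical listing: start knee/hip > 160,
# descend knee < 100 and hip < 150).
_BUILTIN_MDL = """
exercise squat {
    characterization: "Standing upright, descending by flexing knees and hips, then returning to the starting position."
    phase 1 {
        description: "Starting position"
        conditions:
            knee_angle > 160
            hip_angle > 160
    }
    phase 2 {
        description: "Descending"
        conditions:
            knee_angle < 100
            hip_angle < 150
    }
}

exercise deadlift {
    characterization: "Hip hinge: torso bent forward with straight arms, then extending to stand."
    phase 1 {
        description: "Starting position, torso leaning forward"
        conditions:
            torso_angle < 100
            elbow_angle > 160
    }
    phase 2 {
        description: "Lifting, torso extended"
        conditions:
            torso_angle > 160
            elbow_angle > 160
    }
}

exercise lunge {
    characterization: "Stepping into a lunge by flexing both knees, then returning upright."
    phase 1 {
        description: "Starting position"
        conditions:
            both knee_angle > 160
    }
    phase 2 {
        description: "Stepping"
        conditions:
            both knee_angle < 100
    }
    phase 3 {
        description: "Returning"
        conditions:
            both knee_angle > 160
    }
}

exercise shoulder_press {
    characterization: "Pressing a load from shoulder level to overhead and lowering it back."
    phase 1 {
        description: "Starting position, load at shoulders"
        conditions:
            elbow_angle < 70
            shoulder_angle < 70
    }
    phase 2 {
        description: "Pressing overhead"
        conditions:
            elbow_angle > 160
            shoulder_angle > 160
            hands_and_elbows_above_head
    }
    phase 3 {
        description: "Lowering"
        conditions:
            elbow_angle < 70
            shoulder_angle < 70
    }
}

exercise push_up {
    characterization: "From a plank, lowering by bending the elbows and pushing back up."
    phase 1 {
        description: "Starting position, arms extended"
        conditions:
            elbow_angle > 150
            horizontal_alignment
    }
    phase 2 {
        description: "Lowering"
        conditions:
            elbow_angle < 100
            horizontal_alignment
    }
    phase 3 {
        description: "Pushing up"
        conditions:
            elbow_angle > 150
            horizontal_alignment
    }
}

exercise pull_up {
    characterization: "Hanging with arms extended, pulling until the chin clears the hands, lowering back."
    phase 1 {
        description: "Hang"
        conditions:
            elbow_angle > 160
            torso_angle > 160
    }
    phase 2 {
        description: "Pulling"
        conditions:
            elbow_angle < 70
            chin_above_hands
    }
    phase 3 {
        description: "Lowering"
        conditions:
            elbow_angle > 160
            torso_angle > 160
    }
}

exercise bent_over_row {
    characterization: "Bent over with a flat torso, rowing the load to the chest and lowering it."
    phase 1 {
        description: "Starting position, arms extended"
        conditions:
            torso_angle < 100
            elbow_angle > 160
    }
    phase 2 {
        description: "Pulling"
        conditions:
            torso_angle < 100
            elbow_angle < 100
    }
    phase 3 {
        description: "Lowering"
        conditions:
            torso_angle < 100
            elbow_angle > 160
    }
}

exercise plank isometric {
    characterization: "Holding a rigid horizontal body line on the forearms or hands."
    min_hold: 2.0
    phase 1 {
        description: "Holding"
        conditions:
            torso_angle > 150
            horizontal_alignment
    }
}

exercise box_jump {
    characterization: "From standing, crouching and jumping onto a box, then stepping down."
    phase 1 {
        description: "Starting position"
        conditions:
            knee_angle > 160
            hip_angle > 160
    }
    phase 2 {
        description: "Jumping"
        conditions:
            knee_angle < 100
            hip_angle < 100
            vertical_rise
    }
    phase 3 {
        description: "Stepping down"
        conditions:
            knee_angle > 160
            hip_angle > 160
            vertical_return
    }
}
"""

_primitive_cache: Optional[dict[str, ExerciseDef]] = None
_compound_cache: dict[str, ExerciseDef] = {}


def _primitives() -> dict[str, ExerciseDef]:
    global _primitive_cache
    if _primitive_cache is None:
        _primitive_cache = {d.name: d for d in parse_mdl(_BUILTIN_MDL)}
    return _primitive_cache


def builtin(name: str) -> ExerciseDef:
    """Return a built-in exercise definition by name.

    Compound exercises (thruster, overhead squat, burpee) are assembled
    through the composition operators from the primitives.
    """
    if name in PRIMITIVE_NAMES:
        return _primitives()[name]
    if name in COMPOUND_NAMES:
        if name not in _compound_cache:
            from . import composition  # compounds are built from primitives
            if name == "thruster":
                d = composition.sequence_compose(
                    "thruster", [builtin("squat"), builtin("shoulder_press")])
            elif name == "overhead_squat":
                d = composition.overlay_compose(
                    "overhead_squat", builtin("squat"),
                    builtin("shoulder_press").phase(2))
            else:
                d = composition.build_burpee("jump_back")
            _compound_cache[name] = d
        return _compound_cache[name]
    raise KeyError(f"unknown exercise {name!r}; "
                   f"known: {', '.join(BUILTIN_NAMES)}")


def all_builtins() -> dict[str, ExerciseDef]:
    return {n: builtin(n) for n in BUILTIN_NAMES}


def builtin_mdl_source() -> str:
    """Canonical MDL text of the nine primitive definitions."""
    return _BUILTIN_MDL


@dataclass(frozen=True)
class ThresholdOverrides:
    """Hierarchical threshold configuration.

    Precedence: ``per_condition`` replacement > ``per_exercise`` tolerance
    > ``global_tolerance``.  Tolerances are in degrees and relax conditions;
    per-condition entries replace a threshold verbatim.
    """

    global_tolerance: float = DEFAULT_TOLERANCE
    per_exercise: dict[str, float] = field(default_factory=dict)
    #: (exercise, phase index, angle_id) -> replacement threshold
    per_condition: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.global_tolerance < 0:
            raise ValueError("global_tolerance must be >= 0")
        if any(t < 0 for t in self.per_exercise.values()):
            raise ValueError("per-exercise tolerances must be >= 0")

    def tolerance_for(self, exercise: str) -> float:
        return self.per_exercise.get(exercise, self.global_tolerance)


STRICT = ThresholdOverrides(global_tolerance=0.0)


def apply_overrides(exercise: ExerciseDef,
                    overrides: ThresholdOverrides) -> ExerciseDef:
    """Produce the *effective* definition under an override configuration.

    Each angle condition either gets its threshold replaced verbatim (a
    matching ``per_condition`` entry) or relaxed by the applicable
    tolerance tau: ``> t`` -> ``> t - tau``, ``< t`` -> ``< t + tau``,
    clamped to [0, 180].  Predicate parameters are untouched.

    Raises
    ------
    MDLSemanticError
        If a per-condition key for this exercise names a phase or angle
        that does not exist.
    """
    tau = overrides.tolerance_for(exercise.name)
    relevant = {k: v for k, v in overrides.per_condition.items()
                if k[0] == exercise.name}
    for (_, phase_idx, angle_id) in relevant:
        if not 1 <= phase_idx <= exercise.n_phases:
            raise MDLSemanticError(
                f"override references missing phase {phase_idx} of "
                f"{exercise.name!r}")
        if angle_id not in {c.angle_id
                            for c in exercise.phase(phase_idx).conditions}:
            raise MDLSemanticError(
                f"override references angle {angle_id!r} absent from "
                f"{exercise.name!r} phase {phase_idx}")

    new_phases = []
    for p in exercise.phases:
        new_conditions = []
        for c in p.conditions:
            key = (exercise.name, p.index, c.angle_id)
            if key in relevant:
                new_conditions.append(replace(c, threshold=relevant[key]))
            elif tau > 0:
                if c.comparator in (">", ">="):
                    t = max(0.0, c.threshold - tau)
                else:
                    t = min(180.0, c.threshold + tau)
                new_conditions.append(replace(c, threshold=t))
            else:
                new_conditions.append(c)
        new_phases.append(replace(p, conditions=tuple(new_conditions)))
    return replace(exercise, phases=tuple(new_phases))
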