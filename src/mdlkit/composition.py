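"""Composition operators for compound exercises.

Two composition modes cover the compound movements of functional training:

* **Sequencing** — concatenating the phase cycles of whole exercises (or
  single phase slices) into one longer cycle.  A thruster is a squat
  followed by a shoulder press; one compound repetition is one full pass
  through every constituent phase in order.

* **Overlay** — conjoining one phase's conditions into every phase of a
  base exercise.  An overhead squat is a squat overlaid with the
  arms-locked-overhead phase of the shoulder press: the squat cycle is
  unchanged but every phase additionally requires the overhead position.

Phase provenance (source exercise and phase index) is retained on each
composed phase for tracing.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence, Union

from .mdl_lang import (ExerciseDef, MDLSemanticError, Phase,
                       PositionalPredicate, phase_satisfiable)

PartType = Union[ExerciseDef, Phase]


class CompositionError(MDLSemanticError):
    pass


def slice_phase(exercise: ExerciseDef, index: int) -> Phase:
    """Address one phase of an exercise (``exercise.phaseN``) for use as a
    transit posture in a sequence."""
    p = exercise.phase(index)
    if p.source is None:
        p = replace(p, source=(exercise.name, index))
    return p


def _tag(p: Phase, exercise_name: str) -> Phase:
    if p.source is None:
        return replace(p, source=(exercise_name, p.index))
    return p


def sequence_compose(name: str, parts: Sequence[PartType],
                     characterization: str = "") -> ExerciseDef:
    """Chain exercises and/or phase slices into one compound cycle.

    Phases are re-numbered contiguously; one repetition of the compound
    is one ordered pass through all constituent phases.  Isometric parts
    must be passed as a phase slice (a transit posture) — a timed hold
    inside a sequence is not supported.
    """
    if len(parts) == 0:
        raise CompositionError("sequence needs at least one part")
    phases: list[Phase] = []
    for part in parts:
        if isinstance(part, ExerciseDef):
            if part.mode == "isometric":
                raise CompositionError(
                    f"isometric part {part.name!r} cannot be sequenced "
                    f"whole; pass a phase slice (slice_phase) to use it "
                    f"as a transit posture")
            phases.extend(_tag(p, part.name) for p in part.phases)
        elif isinstance(part, Phase):
            phases.append(part)
        else:
            raise CompositionError(f"cannot sequence part of type "
                                   f"{type(part).__name__}")
    renumbered = tuple(replace(p, index=i + 1) for i, p in enumerate(phases))
    if len(renumbered) == 1:
        # identity case: a single phase slice is not a valid cycle
        raise CompositionError("a cyclic compound needs >= 2 phases")
    if not characterization:
        srcs = []
        for p in renumbered:
            s = p.source[0] if p.source else "?"
            if not srcs or srcs[-1] != s:
                srcs.append(s)
        characterization = "Sequence of " + " then ".join(srcs) + "."
    return ExerciseDef(name=name, characterization=characterization,
                       phases=renumbered, mode="cyclic")


def _merge(base: Phase, overlay: Phase) -> Phase:
    conditions = list(base.conditions)
    for c in overlay.conditions:
        if c not in conditions:
            conditions.append(c)
    predicates = list(base.predicates)
    for p in overlay.predicates:
        if p not in predicates:
            predicates.append(p)
    return replace(base, conditions=tuple(conditions),
                   predicates=tuple(predicates))


def overlay_compose(name: str, base: ExerciseDef, overlay: Phase,
                    scope: Union[str, Sequence[int]] = "all",
                    characterization: str = "") -> ExerciseDef:
    """Conjoin ``overlay``'s conditions into the in-scope phases of ``base``.

    ``scope`` is ``"all"`` or a list of phase indices.  The phase count is
    unchanged; overlay repetitions can only ever be a subset of base
    repetitions (a monotone restriction).

    Raises
    ------
    CompositionError
        If the conjunction makes any in-scope phase unsatisfiable.
    """
    if scope == "all":
        indices = {p.index for p in base.phases}
    else:
        indices = set(scope)
        missing = indices - {p.index for p in base.phases}
        if missing:
            raise CompositionError(
                f"scope references missing phases {sorted(missing)}")
    new_phases = []
    for p in base.phases:
        if p.index in indices:
            merged = _merge(p, overlay)
            if not phase_satisfiable(merged):
                raise CompositionError(
                    f"overlay makes phase {p.index} of {base.name!r} "
                    f"unsatisfiable")
            new_phases.append(merged)
        else:
            new_phases.append(p)
    if not characterization:
        src = overlay.source[0] if overlay.source else "overlay"
        characterization = (f"{base.characterization} "
                            f"Performed with the {src} overlay held "
                            f"throughout.").strip()
    return ExerciseDef(name=name, characterization=characterization,
                       phases=tuple(new_phases), mode=base.mode,
                       min_hold=base.min_hold)


def compose_from_expr(expr: str, resolver=None) -> ExerciseDef:
    """Build a compound from a compact expression line.

    Two forms are accepted (a small extension over the core language;
    the canonical expanded definition is always available via
    ``render_mdl``)::

        thruster = squat then shoulder_press     # sequencing
        overhead_squat = squat with shoulder_press.phase2   # overlay

    ``then`` operands and the left ``with`` operand are exercise names;
    an operand may address a single phase as ``exercise.phaseN`` (slice).
    ``resolver`` maps a name to an :class:`ExerciseDef` (defaults to the
    built-in library).
    """
    if resolver is None:
        from .exercise_library import builtin as resolver

    def operand(tok: str):
        tok = tok.strip()
        if "." in tok:
            base, _, ph = tok.partition(".")
            if not ph.startswith("phase") or not ph[5:].isdigit():
                raise CompositionError(f"bad phase slice {tok!r}")
            return slice_phase(resolver(base.strip()), int(ph[5:]))
        return resolver(tok)

    if "=" not in expr:
        raise CompositionError("expected 'name = expression'")
    name, _, rhs = expr.partition("=")
    name = name.strip()
    if not name:
        raise CompositionError("compound needs a name")
    if " with " in rhs:
        left, _, right = rhs.partition(" with ")
        base = operand(left)
        overlay = operand(right)
        if isinstance(overlay, ExerciseDef):
            raise CompositionError(
                "the overlay operand must be a phase slice "
                "(exercise.phaseN)")
        if not isinstance(base, ExerciseDef):
            raise CompositionError("the overlay base must be an exercise")
        return overlay_compose(name, base, overlay)
    parts = [operand(tok) for tok in rhs.split(" then ")]
    return sequence_compose(name, parts)


def build_burpee(variant: str = "jump_back") -> ExerciseDef:
    """Assemble a burpee from primitive building blocks.

    Standing -> deadlift starting posture (crouch, hands down) -> plank
    transit -> push-up down/up -> deadlift starting posture -> standing,
    finishing with an explosive vertical jump in the ``jump_back`` variant;
    the lower-impact ``step_back`` variant omits the jump requirement.
    """
    if variant not in ("jump_back", "step_back"):
        raise CompositionError(f"unknown burpee variant {variant!r}")
    from .exercise_library import builtin  # deferred: library builds compounds via us

    squat = builtin("squat")
    deadlift = builtin("deadlift")
    plank = builtin("plank")
    push_up = builtin("push_up")

    standing = replace(slice_phase(squat, 1),
                       description="Standing upright")
    crouch = replace(slice_phase(deadlift, 1),
                     description="Crouch, hands toward the ground")
    plank_transit = replace(slice_phase(plank, 1),
                            description="Plank transit")
    pu_down = slice_phase(push_up, 2)
    pu_up = slice_phase(push_up, 3)
    crouch_back = replace(crouch, description="Crouch, feet forward")

    final = replace(slice_phase(squat, 1), description="Standing up")
    if variant == "jump_back":
        final = replace(
            final,
            description="Standing up with a vertical jump",
            predicates=final.predicates + (
                PositionalPredicate(kind="vertical_rise"),))

    parts = [standing, crouch, plank_transit, pu_down, pu_up, crouch_back,
             final]
    d = sequence_compose(
        "burpee", parts,
        characterization=("From standing, crouching to the floor, kicking "
                          "back to a plank, performing a push-up, returning "
                          "to the crouch and standing up"
                          + (" with a jump." if variant == "jump_back"
                             else ".")))
    return d
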