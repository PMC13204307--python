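"""The Movement Description Language (MDL): parser, renderer, validator.

MDL is a small declarative language for exercise definitions.  An exercise
is an ordered list of movement *phases*; each phase is a conjunction of
angle conditions (thresholds on the five pose-derived angle proxies) and,
optionally, positional predicates (relations between landmark positions
that angles alone cannot express).  Grammar, in EBNF::

    document        : exercise*
    exercise        : "exercise" ID ["isometric"] "{"
                          characterization [min_hold] phase+ "}"
    characterization: "characterization" ":" STRING
    min_hold        : "min_hold" ":" NUMBER          (isometric only; seconds)
    phase           : "phase" INTEGER "{" description "conditions" ":" item+ "}"
    description     : "description" ":" STRING
    item            : condition | predicate
    condition       : ["both"] ANGLE_ID COMPARISON NUMBER
    predicate       : PRED_ID ["(" NUMBER ")"]
    ANGLE_ID        : "knee_angle" | "hip_angle" | "elbow_angle"
                    | "shoulder_angle" | "torso_angle"
    PRED_ID         : "hands_and_elbows_above_head" | "chin_above_hands"
                    | "horizontal_alignment" | "vertical_rise"
                    | "vertical_return"
    COMPARISON      : ">" | "<" | ">=" | "<=" | "≥" | "≤"
    NUMBER          : [0-9]+ ("." [0-9]+)?

Comments run from ``#`` to end of line.  Strings are double-quoted with
``\\"`` as the only escape.  Unicode comparators parse to the same AST as
their ASCII spellings.  A ``both``-prefixed condition must hold on both
body sides (e.g. both knees in a lunge).

A cyclic exercise needs at least two phases with contiguous indices from 1;
an isometric exercise (a hold, e.g. a plank) has exactly one phase and is
counted by time held rather than by cycles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

ANGLE_IDS = ("knee_angle", "hip_angle", "elbow_angle", "shoulder_angle",
             "torso_angle")

#: Positional predicate vocabulary and per-kind default parameter.
#: Parameters are a margin in normalized image units, except
#: horizontal_alignment whose parameter is a maximum tilt in degrees.
PREDICATE_DEFAULTS: dict[str, float] = {
    "hands_and_elbows_above_head": 0.0,
    "chin_above_hands": 0.0,
    "horizontal_alignment": 20.0,
    "vertical_rise": 0.05,
    "vertical_return": 0.05,
}

COMPARATORS = (">", "<", ">=", "<=")
_COMPARATOR_ALIASES = {"≥": ">=", "≤": "<="}


class MDLError(Exception):
    """Base class for MDL language errors."""


class MDLSyntaxError(MDLError):
    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class MDLSemanticError(MDLError):
    pass


@dataclass(frozen=True)
class Condition:
    """An angle threshold, e.g. ``knee_angle > 160``."""

    angle_id: str
    comparator: str  # one of ">", "<", ">=", "<="
    threshold: float
    both_sides: bool = False

    def __post_init__(self) -> None:
        if self.angle_id not in ANGLE_IDS:
            raise MDLSemanticError(f"unknown angle id {self.angle_id!r}")
        if self.comparator not in COMPARATORS:
            raise MDLSemanticError(f"unknown comparator {self.comparator!r}")
        if not (0.0 <= self.threshold <= 360.0):
            raise MDLSemanticError(
                f"threshold {self.threshold} outside [0, 360]")

    def holds(self, value: Optional[float]) -> bool:
        """Evaluate against an angle value; undefined angles never satisfy."""
        if value is None:
            return False
        if self.comparator == ">":
            return value > self.threshold
        if self.comparator == "<":
            return value < self.threshold
        if self.comparator == ">=":
            return value >= self.threshold
        return value <= self.threshold

    def render(self) -> str:
        num = _render_number(self.threshold)
        prefix = "both " if self.both_sides else ""
        return f"{prefix}{self.angle_id} {self.comparator} {num}"


@dataclass(frozen=True)
class PositionalPredicate:
    """A positional check, e.g. ``hands_and_elbows_above_head``."""

    kind: str
    parameter: float = -1.0  # sentinel replaced by the per-kind default

    def __post_init__(self) -> None:
        if self.kind not in PREDICATE_DEFAULTS:
            raise MDLSemanticError(f"unknown predicate {self.kind!r}")
        if self.parameter == -1.0:
            object.__setattr__(self, "parameter", PREDICATE_DEFAULTS[self.kind])
        if self.parameter < 0:
            raise MDLSemanticError("predicate parameter must be >= 0")

    def render(self) -> str:
        if self.parameter == PREDICATE_DEFAULTS[self.kind]:
            return self.kind
        return f"{self.kind}({_render_number(self.parameter)})"


@dataclass(frozen=True)
class Phase:
    """One movement phase: a conjunction of conditions and predicates."""

    index: int
    description: str
    conditions: tuple[Condition, ...]
    predicates: tuple[PositionalPredicate, ...] = ()
    #: (exercise name, phase index) this phase was composed from, if any.
    source: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise MDLSemanticError("phase index must be >= 1")
        if not self.conditions:
            raise MDLSemanticError(
                f"phase {self.index} must have at least one condition")


@dataclass(frozen=True)
class ExerciseDef:
    """A parsed MDL exercise: ordered phases plus counting mode."""

    name: str
    characterization: str
    phases: tuple[Phase, ...]
    mode: str = "cyclic"  # "cyclic" | "isometric"
    min_hold: Optional[float] = None  # seconds, isometric only

    def __post_init__(self) -> None:
        if self.mode not in ("cyclic", "isometric"):
            raise MDLSemanticError(f"unknown mode {self.mode!r}")
        idx = [p.index for p in self.phases]
        if idx != list(range(1, len(idx) + 1)):
            raise MDLSemanticError(
                f"exercise {self.name!r}: phase indices must be contiguous "
                f"from 1, got {idx}")
        if self.mode == "cyclic" and len(self.phases) < 2:
            raise MDLSemanticError(
                f"cyclic exercise {self.name!r} needs >= 2 phases")
        if self.mode == "isometric" and len(self.phases) != 1:
            raise MDLSemanticError(
                f"isometric exercise {self.name!r} needs exactly 1 phase")
        if self.mode == "isometric" and self.min_hold is not None and self.min_hold < 0:
            raise MDLSemanticError("min_hold must be >= 0")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def phase(self, index: int) -> Phase:
        try:
            return self.phases[index - 1]
        except IndexError:
            raise MDLSemanticError(
                f"exercise {self.name!r} has no phase {index}") from None


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"""
    (?P<ws>[ \t\r]+)
  | (?P<comment>\#[^\n]*)
  | (?P<nl>\n)
  | (?P<number>[0-9]+(\.[0-9]+)?)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<string>"(\\"|[^"])*")
  | (?P<cmp>>=|<=|≥|≤|>|<)
  | (?P<punct>[{}():])
""", re.VERBOSE)


@dataclass(frozen=True)
class _Token:
    kind: str
    value: str
    line: int
    column: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    line, col = 1, 1
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise MDLSyntaxError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        value = m.group()
        if kind == "nl":
            line += 1
            col = 1
        else:
            if kind not in ("ws", "comment"):
                if kind == "cmp":
                    value = _COMPARATOR_ALIASES.get(value, value)
                tokens.append(_Token(kind, value, line, col))
            col += len(value)
        pos = m.end()
    tokens.append(_Token("eof", "", line, col))
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def _fail(self, expected: str) -> None:
        t = self.cur
        shown = t.value if t.kind != "eof" else "end of input"
        raise MDLSyntaxError(f"expected {expected}, found {shown!r}",
                             t.line, t.column)

    def accept(self, kind: str, value: Optional[str] = None) -> Optional[_Token]:
        t = self.cur
        if t.kind == kind and (value is None or t.value == value):
            self.i += 1
            return t
        return None

    def expect(self, kind: str, value: Optional[str] = None) -> _Token:
        t = self.accept(kind, value)
        if t is None:
            self._fail(value if value is not None else kind)
        return t

    def string(self) -> str:
        t = self.expect("string")
        return t.value[1:-1].replace('\\"', '"')

    def number(self) -> float:
        return float(self.expect("number").value)

    # grammar productions -------------------------------------------------

    def document(self) -> list[ExerciseDef]:
        defs = []
        while self.cur.kind != "eof":
            defs.append(self.exercise())
        names = [d.name for d in defs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise MDLSemanticError(f"duplicate exercise names: {sorted(dupes)}")
        return defs

    def exercise(self) -> ExerciseDef:
        self.expect("ident", "exercise")
        name = self.expect("ident").value
        isometric = self.accept("ident", "isometric") is not None
        self.expect("punct", "{")
        self.expect("ident", "characterization")
        self.expect("punct", ":")
        characterization = self.string()
        min_hold = None
        if self.accept("ident", "min_hold"):
            self.expect("punct", ":")
            min_hold = self.number()
        phases = []
        seen: set[int] = set()
        while self.cur.kind == "ident" and self.cur.value == "phase":
            ph = self.phase()
            if ph.index in seen:
                raise MDLSemanticError(
                    f"exercise {name!r}: duplicate phase index {ph.index}")
            seen.add(ph.index)
            phases.append(ph)
        if not phases:
            self._fail("at least one phase")
        self.expect("punct", "}")
        if min_hold is not None and not isometric:
            raise MDLSemanticError(
                f"exercise {name!r}: min_hold is only valid with isometric")
        return ExerciseDef(
            name=name, characterization=characterization,
            phases=tuple(sorted(phases, key=lambda p: p.index)),
            mode="isometric" if isometric else "cyclic",
            min_hold=min_hold)

    def phase(self) -> Phase:
        self.expect("ident", "phase")
        idx_tok = self.expect("number")
        if "." in idx_tok.value:
            raise MDLSyntaxError("phase index must be an integer",
                                 idx_tok.line, idx_tok.column)
        index = int(idx_tok.value)
        self.expect("punct", "{")
        self.expect("ident", "description")
        self.expect("punct", ":")
        description = self.string()
        self.expect("ident", "conditions")
        self.expect("punct", ":")
        conditions: list[Condition] = []
        predicates: list[PositionalPredicate] = []
        while True:
            item = self.condition_or_predicate()
            if item is None:
                break
            if isinstance(item, Condition):
                conditions.append(item)
            else:
                predicates.append(item)
        if not conditions and not predicates:
            self._fail("at least one condition")
        if not conditions:
            raise MDLSemanticError(
                f"phase {index} needs at least one angle condition")
        self.expect("punct", "}")
        return Phase(index=index, description=description,
                     conditions=tuple(conditions), predicates=tuple(predicates))

    def condition_or_predicate(self):
        t = self.cur
        if t.kind != "ident":
            return None
        both = False
        if t.value == "both":
            nxt = self.tokens[self.i + 1]
            if nxt.kind == "ident" and nxt.value in ANGLE_IDS:
                self.i += 1
                both = True
                t = self.cur
        if t.value in ANGLE_IDS:
            self.i += 1
            cmp_tok = self.expect("cmp")
            threshold = self.number()
            try:
                return Condition(angle_id=t.value, comparator=cmp_tok.value,
                                 threshold=threshold, both_sides=both)
            except MDLSemanticError as e:
                raise MDLSemanticError(
                    f"line {t.line}: {e}") from None
        if t.value in PREDICATE_DEFAULTS:
            self.i += 1
            param = -1.0
            if self.accept("punct", "("):
                param = self.number()
                self.expect("punct", ")")
            return PositionalPredicate(kind=t.value, parameter=param)
        return None


def parse_mdl(text: str) -> list[ExerciseDef]:
    """Parse MDL source text into exercise definitions.

    Raises :class:`MDLSyntaxError` (with line/column) on malformed input
    and :class:`MDLSemanticError` on structural violations (duplicate
    phase indices, thresholds outside [0, 360], unknown angle ids, ...).
    """
    if not text.strip():
        raise MDLSyntaxError("empty MDL document", 1, 1)
    return _Parser(_tokenize(text)).document()


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_number(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _render_string(s: str) -> str:
    return '"' + s.replace('"', '\\"') + '"'


def render_mdl(defs: list[ExerciseDef]) -> str:
    """Emit canonical MDL text; ``parse_mdl(render_mdl(defs))`` recovers an
    equal structure (phase provenance aside)."""
    out: list[str] = []
    for d in defs:
        head = f"exercise {d.name}"
        if d.mode == "isometric":
            head += " isometric"
        out.append(head + " {")
        out.append(f"    characterization: {_render_string(d.characterization)}")
        if d.min_hold is not None:
            out.append(f"    min_hold: {_render_number(d.min_hold)}")
        for p in d.phases:
            out.append(f"    phase {p.index} {{")
            out.append(f"        description: {_render_string(p.description)}")
            out.append("        conditions:")
            for c in p.conditions:
                out.append(f"            {c.render()}")
            for pr in p.predicates:
                out.append(f"            {pr.render()}")
            out.append("    }")
        out.append("}")
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _interval(conditions: tuple[Condition, ...], angle_id: str) -> tuple[float, float]:
    """Feasible (lo, hi) open-ish interval an angle must lie in, given the
    conjunction; comparator strictness is ignored for satisfiability."""
    lo, hi = 0.0, 180.0
    for c in conditions:
        if c.angle_id != angle_id:
            continue
        if c.comparator in (">", ">="):
            lo = max(lo, c.threshold)
        else:
            hi = min(hi, c.threshold)
    return lo, hi


def phase_satisfiable(phase: Phase) -> bool:
    """Whether some assignment of angles in [0, 180] satisfies every
    condition of the phase (predicates are position-dependent and assumed
    satisfiable)."""
    for aid in {c.angle_id for c in phase.conditions}:
        lo, hi = _interval(phase.conditions, aid)
        if lo >= hi:
            return False
    return True


def validate_def(exercise: ExerciseDef) -> list[str]:
    """Return warnings (never raises): unsatisfiable phases, thresholds
    outside [0, 180], identical adjacent phases."""
    warnings: list[str] = []
    for p in exercise.phases:
        if not phase_satisfiable(p):
            warnings.append(
                f"{exercise.name} phase {p.index}: conditions are "
                f"unsatisfiable (empty angle interval)")
        for c in p.conditions:
            if c.threshold > 180.0:
                warnings.append(
                    f"{exercise.name} phase {p.index}: threshold "
                    f"{_render_number(c.threshold)} exceeds the angle "
                    f"range [0, 180]")
    ps = exercise.phases
    pairs = list(zip(ps, ps[1:]))
    if exercise.mode == "cyclic" and len(ps) > 2:
        pairs.append((ps[-1], ps[0]))  # the cycle wraps: last is adjacent to first
    for a, b in pairs:
        if set(a.conditions) == set(b.conditions) and \
           set(a.predicates) == set(b.predicates):
            warnings.append(
                f"{exercise.name} phases {a.index} and {b.index}: identical "
                f"adjacent condition sets (cycle endpoints)")
    return warnings
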