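# Methods

This note documents the model behind `mdlkit`, the choices made where the
design was genuinely open, and what the synthetic evaluation does and
does not show.

## Angle proxies and coordinate conventions

All conditions are expressed over five interior angles computed from
triplets of body landmarks in the standard 33-keypoint monocular layout.
These are *approximate kinematic proxies*, not biomechanical joint
angles: monocular landmarks do not coincide with anatomical joint
centers, and reported knee-flexion errors of monocular estimators reach
tens of degrees in unfavorable views.  The framework is designed around
that fact — thresholds are coarse (tens of degrees apart) and tolerances
are wide.

Conventions:

* Normalized image coordinates, origin top-left, y increasing downward;
  "above" therefore means smaller y.  This matches the convention of the
  estimators that produce the 33-point layout.
* Angles use (x, y) only, unless all three landmarks of a triplet carry a
  z coordinate; the monocular setting makes planar angles the honest
  default.
* The canonical triplets are left-sided.  `side_mode` selects
  `as_printed` (left), `mirrored` (contralateral indices), or
  `both_min`/`both_max` (elementwise combination).  A subject filmed from
  their right side is consumed with `side_mode="mirrored"`.  Conditions
  flagged `both` (the lunge's knees) must hold on both sides.
* `hip_angle` pivots at the *contralateral* hip (θ(k23,k24,k25)), which
  is unusual but kept as the canonical definition; a sagittal
  shoulder–hip–knee variant is available via
  `angles_from_frame(..., sagittal_hip=True)` for users who want a
  conventional hip-flexion reading.
* Degenerate triplets (coincident landmarks) and absent landmarks make
  exactly the dependent angles *undefined* rather than raising: the
  temporal layer, not the math layer, decides how to cope.

Positional predicates cover relations angles cannot express: hands and
elbows above the head (overhead lockout), chin above the hands (pull-up
top), shoulder–hip segment within a tilt budget of horizontal (plank and
push-up posture, default 20°, inclusive), and center-of-mass rise/return
for jumps.  Center of mass is proxied by the hip midpoint ordinate.  The
vertical predicates are measured against a baseline recorded while the
machine was last in phase 1 (the standing posture), with a default
displacement of 0.05 normalized units — about 5% of image height, a
clear jump at typical framing; no principled constant exists, so this is
a package choice.

## The language

The grammar (see `mdl_lang`) is deliberately tiny: exercises contain one
characterization and one or more phases; phases contain a description and
a conjunction of conditions.  Extensions beyond the minimal core, each
made because the built-in definitions need them:

* `torso_angle` is part of the condition vocabulary (the deadlift,
  pull-up, row and plank are torso-gated).
* Positional predicates are a closed keyword set inside the conditions
  block, with an optional parenthesized parameter.
* Isometric exercises are declared with an `isometric` keyword and an
  optional `min_hold` (seconds); they have exactly one phase and are
  counted by hold duration, not cycles.
* Comparators accept ASCII (`>=`, `<=`) and Unicode (`≥`, `≤`) spellings
  and parse identically.
* Thresholds are accepted up to 360 at parse time; validation *warns*
  above 180 (outside the angle range) rather than rejecting, since a
  user may be mid-edit.

The renderer emits a canonical form with the round-trip guarantee
`parse(render(defs)) == defs`, property-tested over randomly generated
definitions.  One caveat: string literals support `\"` as their only
escape; backslashes are not part of the string alphabet.

## The engine

Each definition runs as a strict-cycle FSM.  Per frame:

1. If the *expected* phase (next in the cycle) is active, advance to it.
   When current and expected are both active under relaxed thresholds,
   expected wins — a forward-progress tie-break that makes overlapping
   tolerance bands harmless.
2. Otherwise, if the current phase is still active, stay.
3. Otherwise adaptive phase persistence retains the current phase for up
   to N frames (default 4, the midpoint of the typical 3–5 window;
   configurable 0–30).  Any non-matching frame consumes persistence,
   whether the cause is dropout or an intermediate posture.  On
   exhaustion the machine drops to `None`, resets the cycle expectation,
   and — if a cycle was in progress — logs a *false transition*.

Only current-or-expected phases are ever matched, so phases cannot be
skipped; the machine also never fabricates a phase at trajectory start.
A repetition is counted at final-phase entry after an ordered traversal
(default), or at the return to phase 1 under
`count_on="return_to_start"` — the temporal semantics are not uniquely
determined by the cycle structure, so both are provided; the default was
chosen because it emits the event at the most distinctive posture of the
movement.  Counting is conservative by construction: degradation
(dropout) can only lose matches, never create them, so errors are missed
repetitions rather than false positives.  Heavy landmark *jitter* is the
one exception — noise oscillating across a threshold can re-trigger a
cycle; at realistic jitter (≤ ~0.005 normalized units) this does not
occur in the synthetic benchmark, and the persistence mechanism is
deliberately not a debouncer or low-pass filter.

Isometric counting: the hold-frame counter accumulates while the phase is
active (persistence bridges short gaps), one repetition fires when it
reaches `min_hold × fps` (plank default 2 s — the built-in ships a
nominal hold; adjust per protocol), and re-arming requires the phase to
stay inactive for at least N frames.

Threshold hierarchy: a global tolerance τ (default 30°) relaxes every
condition toward satisfiability (`> t` → `> t − τ`, `< t` → `< t + τ`,
clamped to [0, 180]); per-exercise tolerances override the global one,
and per-condition replacement thresholds override both.  Tolerance
*relaxes* rather than tightens because its purpose is absorbing pose
uncertainty and reduced mobility.  Predicate parameters are never
relaxed.  τ = 0 gives exact-threshold semantics for tests.

## Built-in definitions

The nine primitives use the reference thresholds (squat start/descend at
160/100–150 per the canonical squat listing; where prose and listing
differ, the listing wins, and overrides can restore alternatives).  Two
judgment calls: the bent-over row keeps its `torso < 100` condition in
all three phases (the row is performed bent over throughout, even though
only the elbows change), and the pull-up's permitted slight torso lean is
advisory — a permission, not a requirement — so it is not a transition
condition.  The plank's torso threshold (150°) is chosen by analogy with
the other extended-posture conditions; no canonical number exists.

Compounds: the thruster is the squat cycle followed by the shoulder-press
cycle (5 phases — the built-in squat has two phases); the overhead squat
overlays the press's lockout phase conditions onto every squat phase
(monotone restriction: it can only count a subset of what the squat
counts); the burpee chains standing → crouch (deadlift start posture) →
plank transit → push-up down/up → crouch → standing, with a
`vertical_rise` requirement on the final phase in the jump-back variant
and without it in the step-back variant.  The plank inside the burpee is
a transit posture (≥ 1 frame), not a timed hold.  Phase slices are
addressed as `exercise.phaseN`; the compact expression forms
`name = A then B` and `name = A with B.phaseN` build compounds from the
library.  Sequencing is associative up to renumbering, and parts may
dwell freely between segments (no same-frame hand-off requirement).

## The synthetic motion generator

A planar sagittal stick figure with fixed segment ratios (thigh = shank =
0.15, torso 0.22, upper arm 0.10, forearm 0.085 in normalized units) is
posed by closed-form inverse kinematics from angle targets.  The
contralateral hip and shoulder sit a fixed 0.03 from their partners, with
their direction solved by the law of sines so that the canonical triplets
— which pass through these points — evaluate *exactly* to their targets;
the remaining right-side landmarks are translated copies, making the two
sides agree by construction.  Because `hip_angle` and `torso_angle` share
the contralateral-hip placement, a single keyframe targets at most one of
them (no built-in phase constrains both).

Exercises are keyframe recipes: phase-labelled angle-target waypoints
with posture parameters (torso lean, arm elevation, whole-body shift for
jumps) on three templates — upright, horizontal support (push-up/plank:
toes anchored, the body a rigid line riding on the arms; at full arm
extension the shoulder–hip tilt is ≈ 17°, inside the 20° alignment
budget), and hanging (pull-up: wrists fixed at a bar, body height driven
by elbow flexion, so the chin clears the hands exactly when the pull is
deep).  Between compatible keyframes the generator eases *in angle
space* with half-cosine ramps, so every intermediate frame is itself an
exact IK solution; across template switches (burpee) it blends rendered
landmark positions instead.  Repetition windows and per-frame intended
phases are recorded exactly; lead-in/lead-out standing frames bracket the
reps.  Default tempo: 40 frames per repetition at 30 fps (≈ 1.3 s — a
brisk but realistic cadence), with optional fractional tempo jitter per
rep.

Degradation models: i.i.d. Gaussian landmark jitter (`noise_sd`,
normalized units) and dropout bursts (landmarks marked absent over frame
intervals, all or a subset).  The generator emulates the *structure* of
real failure modes, not any specific estimator's error distribution; it
is deterministic given the seed.

**What passing synthetic tests shows — and does not.**  Exact recovery of
planned repetitions at zero noise shows the language, engine, thresholds
and composition operators are mutually consistent and that counting is
driven by the intended kinematic events.  It does not certify accuracy on
real video: real pose errors are correlated in time and space, viewpoint-
dependent, and landmark-specific, none of which the i.i.d. jitter model
captures.  The evaluation-table arithmetic (97.2% overall, 98.8% mean
per-exercise) is computed *from the reference per-exercise counts as
inputs*; reproducing it validates the statistics pipeline, not the
vision pipeline.

## Evaluation statistics

Counting accuracy is detected/ground-truth in percent; per-exercise
values are rounded to the nearest integer (half-up), the overall and the
mean-of-per-exercise values to one decimal.  Detected counts above ground
truth are clamped in the accuracy column and reported separately as
false positives.  Confidence intervals are exact Clopper–Pearson from
Beta quantiles, with the closed-form boundaries (lower =
100·(α/2)^(1/n) at full success); the test suite cross-checks them
against an independent bisection on binomial tail sums.  Exact intervals
are conservative: empirical coverage exceeds the nominal level.  The
persistence ablation table is plain arithmetic,
100·(GT − errors)/GT at one decimal.

## Numerical choices and limitations

* `compute_angle` uses the arccos formula with the cosine clipped to
  [−1, 1]; worst-case deviation from an atan2 formulation is < 1e-6° on
  random triples, and ~1e-6° of noise near exactly-parallel rays.
* Strict inequalities are strict: `knee_angle > 160` is false at exactly
  160.  Tilt budgets (`horizontal_alignment`) are inclusive.
* The generator's frontal view is not implemented — planar sagittal
  geometry cannot express it honestly; `view` accepts left/right
  sagittal only.
* Isometric definitions cannot be sequenced whole inside compounds (pass
  a phase slice); timed holds mid-sequence are out of scope.
* The engine processes frames in order with O(1) state — streaming-safe —
  but no real-time capture loop is included.
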