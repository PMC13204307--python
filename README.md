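# mdlkit

A **Movement Description Language (MDL)** for functional-training
analysis: exercise definitions written in a small declarative language
compile to finite-state machines over pose-landmark joint-angle proxies,
giving interpretable phase detection and repetition counting with no
training data.

The package is aimed at people building camera-based exercise analysis —
sports scientists, physiotherapy tooling developers, fitness-app
engineers — who want counting logic they can read, edit and reason
about, instead of a black-box recognizer.  It consumes per-frame body
landmarks in the common 33-keypoint monocular-estimator layout from *any*
pose estimator (it does not do pose estimation itself) and ships with a
synthetic stick-figure motion generator so everything is testable without
video data.

## The model

Five **pose-derived angle proxies** are computed per frame from landmark
triplets (θ at the middle point):

| proxy | triplet | meaning |
|---|---|---|
| `knee_angle` | θ(k23, k25, k27) | hip–knee–ankle |
| `hip_angle` | θ(k23, k24, k25) | hip–hip–knee |
| `elbow_angle` | θ(k11, k13, k15) | shoulder–elbow–wrist |
| `shoulder_angle` | θ(k11, k12, k13) | shoulder–shoulder–elbow |
| `torso_angle` | θ(k11, k23, k24) | shoulder–hip–hip |

with θ(a, b, c) = arccos( (b→a · b→c) / (|b→a| |b→c|) ), in degrees.

An **exercise definition** is an ordered list of *phases*, each a
conjunction of angle thresholds and positional predicates:

```
exercise squat {
    characterization: "Standing upright, descending by flexing knees and hips,
                       then returning to the starting position."
    phase 1 {
        description: "Starting position"
        conditions:
            knee_angle > 160      # default, adjustable
            hip_angle > 160
    }
    phase 2 {
        description: "Descending"
        conditions:
            knee_angle < 100
            hip_angle < 150
    }
}
```

The definition runs as a strict-cycle **finite-state machine**: a phase is
active when all its conditions hold; the machine only advances to the
next expected phase, and a repetition is counted when the final phase of
the cycle activates after an ordered traversal.  **Adaptive phase
persistence** retains the last valid phase for up to N frames (default 4)
when nothing matches, bridging transient landmark dropouts without
hysteresis or smoothing.  A hierarchical **threshold tolerance** (default
30°, relaxing every condition toward satisfiability) absorbs pose noise
and individual mobility differences; per-exercise and per-condition
overrides take precedence.

Compound movements are built from primitives, not redefined: a *thruster*
is `squat then shoulder_press` (phase sequencing), an *overhead squat* is
`squat with shoulder_press.phase2` (condition overlay), and a *burpee*
chains standing, crouch, plank, push-up and jump phase slices.  Twelve
exercises ship built in: squat, deadlift, lunge, shoulder press, push-up,
pull-up, bent-over row, plank (an isometric, counted by hold time), box
jump, thruster, overhead squat, burpee.

## Worked example

Generate a clean synthetic 5-rep squat (33-landmark JSONL plus exact
ground-truth rep intervals) and count it:

```bash
$ mdl simulate squat --reps 5 --seed 1 --out sq.jsonl --ground-truth sq_gt.csv
wrote 220 frames, 5 reps
$ mdl count sq.jsonl squat
rep 1 at frame 28
rep 2 at frame 68
rep 3 at frame 108
rep 4 at frame 148
rep 5 at frame 188
5
```

Each `rep i at frame f` line marks the frame where the descent phase
activated after a full ordered cycle; the final `5` is the repetition
count, matching the generator's plan.  The ground-truth file lists the
five rep windows (`squat,1,10,49`, ...) and every counted event falls
inside its window.

Summarizing a per-video results table (`exercise,gt_reps,detected_reps`)
with `mdl evaluate results.csv` prints per-exercise accuracies with exact
95% Clopper–Pearson intervals:

```
Exercise            GT   Det   Acc%            95% CI  FP
squat              572   546     95      [93.4-97.0%]   0
...
Total             1916  1863   97.2      [96.4-97.9%]
Mean per-exercise accuracy: 98.8%
```

The same operations are available as library functions
(`mdlkit.run`, `mdlkit.summarize`, `mdlkit.generate_trajectory`, ...);
see `docs/methods.md` for the underlying model and its assumptions.

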