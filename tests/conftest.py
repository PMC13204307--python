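import pytest

from mdlkit import builtin, run
from mdlkit.fsm_engine import EngineConfig
from mdlkit.synthetic_motion import MotionSpec, generate_trajectory

#: Per-exercise (ground truth, detected) repetition counts of a large
#: multi-source video evaluation, used as arithmetic fixtures.
EVAL_COUNTS = [
    ("squat", 572, 546),
    ("deadlift", 379, 360),
    ("lunge", 42, 42),
    ("shoulder_press", 356, 355),
    ("push_up", 238, 234),
    ("pull_up", 94, 94),
    ("bent_over_row", 12, 12),
    ("plank", 9, 9),
    ("box_jump", 14, 14),
    ("thruster", 33, 33),
    ("overhead_squat", 141, 138),
    ("burpee", 26, 26),
]


@pytest.fixture(scope="session")
def squat_def():
    return builtin("squat")


@pytest.fixture(scope="session")
def clean_squat():
    """A clean 5-rep squat trajectory with its ground truth."""
    return generate_trajectory(MotionSpec(exercise="squat", reps=5, seed=3))


@pytest.fixture(scope="session")
def clean_squat_events(clean_squat, squat_def):
    traj, _ = clean_squat
    count, events, trace = run(traj, squat_def, EngineConfig())
    assert count == 5
    return events
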