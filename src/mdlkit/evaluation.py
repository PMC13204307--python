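"""Repetition-counting evaluation statistics.

Per-exercise and overall counting accuracy with exact (Clopper-Pearson)
binomial confidence intervals, plus the persistence-ablation arithmetic.
Conventions: per-exercise accuracies are rounded to the nearest integer
percent, the overall and mean per-exercise accuracies to one decimal —
the usual presentation for this kind of evaluation table.  Detected
counts above ground truth are clamped for the accuracy column and
reported separately as false positives (counting errors are overwhelmingly
missed repetitions; an over-count is flagged, not rewarded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import beta


@dataclass(frozen=True)
class VideoResult:
    """Ground-truth vs. detected repetitions for one video."""

    exercise: str
    gt_reps: int
    detected_reps: int

    def __post_init__(self) -> None:
        if self.gt_reps < 0 or self.detected_reps < 0:
            raise ValueError("counts must be >= 0")


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def accuracy(gt: int, detected: int, rounding: str = "one_decimal") -> float:
    """Percent of ground-truth repetitions detected.

    ``rounding``: ``"one_decimal"`` (overall convention), ``"integer"``
    (per-exercise convention), or ``"none"``.  ``detected`` is clamped to
    ``gt`` (see module docstring).
    """
    if gt <= 0:
        raise ValueError("ground-truth count must be > 0")
    pct = 100.0 * min(detected, gt) / gt
    if rounding == "one_decimal":
        return _round_half_up(pct, 1)
    if rounding == "integer":
        return _round_half_up(pct, 0)
    if rounding == "none":
        return pct
    raise ValueError(f"unknown rounding {rounding!r}")


def clopper_pearson(successes: int, trials: int,
                    level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval, in percent.

    Beta-quantile form: lower = B(alpha/2; x, n-x+1), upper =
    B(1-alpha/2; x+1, n-x), with the closed-form boundary cases
    lower = 0 at x = 0 and upper = 100 at x = n (where the non-trivial
    bound reduces to 100*(alpha/2)**(1/n)).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    if successes == 0:
        lower = 0.0
    else:
        lower = 100.0 * float(beta.ppf(alpha / 2, successes,
                                       trials - successes + 1))
    if successes == trials:
        upper = 100.0
    else:
        upper = 100.0 * float(beta.ppf(1 - alpha / 2, successes + 1,
                                       trials - successes))
    return lower, upper


@dataclass(frozen=True)
class EvalSummary:
    """Aggregated evaluation: one row per exercise plus overall figures."""

    per_exercise: pd.DataFrame  # exercise, gt, detected, accuracy, ci_low, ci_high, false_positives
    overall_gt: int
    overall_detected: int
    overall_accuracy: float          # percent, one decimal
    overall_ci: tuple[float, float]  # percent
    mean_per_exercise_accuracy: float  # percent, one decimal
    level: float = 0.95

    def to_text(self) -> str:
        lines = [f"{'Exercise':<16}{'GT':>6}{'Det':>6}{'Acc%':>7}"
                 f"{'95% CI':>18}{'FP':>4}"]
        for _, r in self.per_exercise.iterrows():
            ci = f"[{r['ci_low']:.1f}-{r['ci_high']:.1f}%]"
            lines.append(f"{r['exercise']:<16}{r['gt']:>6}{r['detected']:>6}"
                         f"{r['accuracy']:>7.0f}{ci:>18}"
                         f"{r['false_positives']:>4}")
        ci = f"[{self.overall_ci[0]:.1f}-{self.overall_ci[1]:.1f}%]"
        lines.append(f"{'Total':<16}{self.overall_gt:>6}"
                     f"{self.overall_detected:>6}"
                     f"{self.overall_accuracy:>7.1f}{ci:>18}")
        lines.append(f"Mean per-exercise accuracy: "
                     f"{self.mean_per_exercise_accuracy:.1f}%")
        return "\n".join(lines)


def summarize(results: Sequence[VideoResult], level: float = 0.95,
              exercise_order: Optional[Sequence[str]] = None) -> EvalSummary:
    """Aggregate per-video counts into the evaluation table.

    Rows are grouped by exercise (order of first appearance unless
    ``exercise_order`` is given); the result is invariant to permutations
    of the input rows.
    """
    if not results:
        raise ValueError("no results to summarize")
    agg: dict[str, list[int]] = {}
    for r in results:
        g = agg.setdefault(r.exercise, [0, 0, 0])
        g[0] += r.gt_reps
        g[1] += min(r.detected_reps, r.gt_reps)
        g[2] += max(0, r.detected_reps - r.gt_reps)
    order = list(exercise_order) if exercise_order is not None \
        else sorted(agg)
    missing = set(agg) - set(order)
    if missing:
        raise ValueError(f"exercise_order missing {sorted(missing)}")

    rows = []
    for ex in order:
        gt, det, fp = agg[ex]
        lo, hi = clopper_pearson(det, gt, level)
        rows.append({"exercise": ex, "gt": gt, "detected": det,
                     "accuracy": accuracy(gt, det, "integer"),
                     "ci_low": lo, "ci_high": hi, "false_positives": fp})
    df = pd.DataFrame(rows)
    total_gt = int(df["gt"].sum())
    total_det = int(df["detected"].sum())
    overall = accuracy(total_gt, total_det, "one_decimal")
    mean_acc = _round_half_up(float(df["accuracy"].mean()), 1)
    return EvalSummary(per_exercise=df, overall_gt=total_gt,
                       overall_detected=total_det, overall_accuracy=overall,
                       overall_ci=clopper_pearson(total_det, total_gt, level),
                       mean_per_exercise_accuracy=mean_acc, level=level)


def ablation_report(gt_total: int, errors_without: int,
                    errors_with: int) -> pd.DataFrame:
    """Persistence ablation table: accuracy with and without the adaptive
    phase-persistence mechanism, from total error counts."""
    if gt_total <= 0:
        raise ValueError("gt_total must be > 0")
    if not (0 <= errors_without <= gt_total and 0 <= errors_with <= gt_total):
        raise ValueError("error counts must be in [0, gt_total]")
    rows = []
    for setting, errs in (("without_persistence", errors_without),
                          ("with_persistence", errors_with)):
        rows.append({"setting": setting, "false_transitions": errs,
                     "accuracy": _round_half_up(
                         100.0 * (gt_total - errs) / gt_total, 1)})
    return pd.DataFrame(rows)


def read_results_table(path) -> list[VideoResult]:
    """Read a results CSV with columns exercise, video_id (optional),
    gt_reps, detected_reps."""
    df = pd.read_csv(path)
    required = {"exercise", "gt_reps", "detected_reps"}
    if not required.issubset(df.columns):
        raise ValueError(f"results table needs columns {sorted(required)}")
    if df.empty:
        raise ValueError("results table is empty")
    return [VideoResult(exercise=str(r.exercise), gt_reps=int(r.gt_reps),
                        detected_reps=int(r.detected_reps))
            for r in df.itertuples()]
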