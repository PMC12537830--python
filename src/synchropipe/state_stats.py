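"""State-level comparisons and open-field behaviour metrics.

Recording-level values (mean firing rate, pair-class mean correlation, ...)
are compared between disease states of the same animals with the classical
paired t-test (df = n_pairs - 1); bar-plot style summaries are mean ± SEM.
Percent change is always 100 * (after - before) / before.

Behaviour: full-body rotations are counted as accumulated net 2*pi heading
excursions (hysteresis counter, invariant to heading offset and to sampling
refinement) and reported per 10 minutes; locomotion is the summed Euclidean
path length of the tracked trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_sessions import ValidationError

__all__ = [
    "Trajectory",
    "TTestResult",
    "StateComparison",
    "percent_change",
    "mean_sem",
    "paired_t",
    "compare_states",
    "rotations",
    "path_length",
]

TWO_PI = 2.0 * np.pi


@dataclass
class Trajectory:
    """Tracked open-field trajectory: positions and unwrapped heading."""

    t_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading_rad: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.heading_rad = np.asarray(self.heading_rad, float)
        if not (self.t_s.shape == self.x.shape == self.y.shape == self.heading_rad.shape):
            raise ValidationError("trajectory columns must be aligned")
        if self.t_s.size >= 2 and np.any(np.diff(self.t_s) <= 0):
            raise ValidationError("timestamps must be strictly increasing")


def percent_change(before: float, after: float) -> float:
    """100 * (after - before) / before; undefined (NaN, warned) for before <= 0."""
    if before <= 0:
        warnings.warn("percent_change undefined for non-positive baseline", stacklevel=2)
        return float("nan")
    return 100.0 * (after - before) / before


def mean_sem(values) -> tuple[float, float]:
    """Sample mean and standard error (sd/sqrt(n)); SEM is NaN for n = 1."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValidationError("mean_sem of empty input")
    mean = float(values.mean())
    if values.size == 1:
        return mean, float("nan")
    return mean, float(values.std(ddof=1) / np.sqrt(values.size))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t(values_a, values_b, alternative: str = "two-sided") -> TTestResult:
    """Classical paired t-test on recording/animal-matched values.

    ``alternative`` is 'two-sided', 'greater' (a > b) or 'less'.  Constant
    nonzero differences have no within-pair variance; the result is flagged
    degenerate (t signed infinite, p = 0 in the favoured direction).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    if a.size < 2:
        raise ValidationError("paired t-test needs n >= 2")
    diff = a - b
    df = a.size - 1
    if diff.std(ddof=1) == 0.0:
        if diff[0] == 0.0:
            p = 1.0 if alternative == "two-sided" else 0.5
            return TTestResult(0.0, df, p)
        t = float(np.inf * np.sign(diff[0]))
        favoured = (
            alternative == "two-sided"
            or (alternative == "greater" and diff[0] > 0)
            or (alternative == "less" and diff[0] < 0)
        )
        return TTestResult(t, df, 0.0 if favoured else 1.0, degenerate=True)
    res = stats.ttest_rel(a, b, alternative=alternative)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


@dataclass
class StateComparison:
    metric: str
    state_a: str
    state_b: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    pct_change: float
    t: float
    df: int
    p: float
    tails: str

    def as_row(self) -> dict:
        return self.__dict__.copy()


def compare_states(
    metric: str,
    state_a: str,
    values_a,
    state_b: str,
    values_b,
    alternative: str = "two-sided",
) -> StateComparison:
    """Paired comparison of a recording-level metric between two states.

    Percent change is from state_a to state_b on the state means; the tail
    choice is recorded in the output row.
    """
    mean_a, sem_a = mean_sem(values_a)
    mean_b, sem_b = mean_sem(values_b)
    test = paired_t(values_b, values_a, alternative=alternative)
    pct = percent_change(mean_a, mean_b) if mean_a > 0 else float("nan")
    return StateComparison(
        metric=metric,
        state_a=state_a,
        state_b=state_b,
        mean_a=mean_a,
        sem_a=sem_a,
        mean_b=mean_b,
        sem_b=sem_b,
        pct_change=pct,
        t=test.t,
        df=test.df,
        p=test.p,
        tails=alternative,
    )


def rotations(trajectory: Trajectory, per_s: float = 600.0) -> tuple[float, float]:
    """(clockwise, counterclockwise) full-turn counts per ``per_s`` seconds.

    A turn is a completed net 2*pi heading excursion, counted with an anchor
    that advances by 2*pi per completed turn (hysteresis), so jitter around a
    crossing is never double-counted.  Counterclockwise is heading-positive.
    Counts are integers before normalisation to the 10 min convention.
    """
    theta = trajectory.heading_rad
    if theta.size < 2:
        raise ValidationError("rotations needs at least 2 samples")
    anchor = theta[0]
    cw = ccw = 0
    for th in theta[1:]:
        while th - anchor >= TWO_PI:
            ccw += 1
            anchor += TWO_PI
        while th - anchor <= -TWO_PI:
            cw += 1
            anchor -= TWO_PI
    duration = trajectory.t_s[-1] - trajectory.t_s[0]
    if duration <= 0:
        raise ValidationError("trajectory has no duration")
    scale = per_s / duration
    return cw * scale, ccw * scale


def path_length(trajectory: Trajectory) -> float:
    """Total travelled distance: sum of consecutive Euclidean steps."""
    if trajectory.t_s.size < 2:
        return 0.0
    return float(np.sum(np.hypot(np.diff(trajectory.x), np.diff(trajectory.y))))


def comparison_table(comparisons: list[StateComparison]) -> pd.DataFrame:
    cols = [
        "metric",
        "state_a",
        "state_b",
        "mean_a",
        "sem_a",
        "mean_b",
        "sem_b",
        "pct_change",
        "t",
        "df",
        "p",
        "tails",
    ]
    return pd.DataFrame([c.as_row() for c in comparisons], columns=cols)
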