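"""Engagement dynamics: windowed probability of engagement and disengagement time.

A session yields a time-ordered sequence of per-trial engaged/distracted
labels.  A causal (backward-looking) rectangular moving window — length 5
min, stepped every 1 min by default — converts those labels into a
probability-of-engagement trace: at evaluation time t, the percentage of
trials whose active period *started* within (t - L, t].  The animal is
declared disengaged at the earliest evaluation time whose probability
falls below a threshold (50% by default).

The window is causal so the estimate at time t uses only the preceding L
minutes, which is what makes the statistic usable during a live session.
Startup windows (t < L) are truncated at the session start rather than
skipped; windows containing no trials yield missing values, never 0%,
since a spurious 0% would immediately trigger the disengagement rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import DISTRACTED, ENGAGED


@dataclass(frozen=True)
class EngagementSeries:
    """Time-ordered per-trial labels; times are active-period starts in seconds."""

    trials: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        starts = [t for t, _ in self.trials]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("trial start times must be strictly increasing")
        for _, label in self.trials:
            if label not in (ENGAGED, DISTRACTED):
                raise ValueError(f"bad label {label!r}")

    @classmethod
    def from_lists(cls, starts_s: Sequence[float],
                   labels: Sequence[str]) -> "EngagementSeries":
        if len(starts_s) != len(labels):
            raise ValueError("starts and labels must have equal length")
        return cls(tuple(zip([float(s) for s in starts_s], labels)))


@dataclass(frozen=True)
class DynamicsConfig:
    """Moving-window parameters.

    window_length : minutes — span of the causal window (default 5)
    step : minutes — spacing of evaluation times (default 1)
    threshold : percent — disengagement cutoff on the probability (default 50)
    min_consecutive : windows — how many consecutive sub-threshold windows
        are required before declaring disengagement (default 1, i.e. first
        crossing)
    """

    window_length: float = 5.0
    step: float = 1.0
    threshold: float = 50.0
    min_consecutive: int = 1

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.step <= 0:
            raise ValueError("window_length and step must be positive")
        if not (0.0 < self.threshold < 100.0):
            raise ValueError("threshold must be strictly between 0 and 100")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")


@dataclass(frozen=True)
class EngagementTrace:
    """Probability-of-engagement series on the evaluation grid.

    ``probabilities`` holds NaN where the window contained no trials;
    ``n_trials`` gives the per-window trial counts; ``truncated`` flags
    startup windows shorter than the full window length.
    """

    eval_times_min: np.ndarray
    probabilities_pct: np.ndarray
    n_trials: np.ndarray
    truncated: np.ndarray
    disengagement_min: float | None = field(default=None)


def probability_of_engagement(n_engaged: int, n_total: int) -> float:
    """Percentage of engaged trials among a window's total trials."""
    if n_total < 1:
        raise ValueError("probability of engagement is undefined for 0 trials")
    if not (0 <= n_engaged <= n_total):
        raise ValueError("need 0 <= n_engaged <= n_total")
    return 100.0 * n_engaged / n_total


def engagement_trace(series: EngagementSeries,
                     cfg: DynamicsConfig = DynamicsConfig(),
                     session_end_s: float | None = None) -> EngagementTrace:
    """Causal moving-window probability of engagement over a session.

    Evaluation times run t = step, 2*step, ... up to the session end (the
    last trial start, unless ``session_end_s`` extends it).  Each window is
    (t - window_length, t] in minutes, truncated at the session start;
    trials are assigned by active-period start time.  Windows holding no
    trials produce NaN.  The returned trace already carries the
    disengagement time under ``cfg``.
    """
    if not series.trials:
        raise ValueError("series must contain at least one trial")
    starts_min = np.array([t for t, _ in series.trials]) / 60.0
    engaged = np.array([lab == ENGAGED for _, lab in series.trials])

    end_min = float(starts_min[-1])
    if session_end_s is not None:
        end_min = max(end_min, session_end_s / 60.0)
    n_steps = int(np.floor(end_min / cfg.step + 1e-9))
    if n_steps < 1:
        n_steps = 1
    eval_times = cfg.step * np.arange(1, n_steps + 1)

    probs = np.full(n_steps, np.nan)
    counts = np.zeros(n_steps, dtype=int)
    trunc = eval_times < cfg.window_length
    for i, t in enumerate(eval_times):
        in_win = (starts_min > t - cfg.window_length) & (starts_min <= t)
        n = int(in_win.sum())
        counts[i] = n
        if n > 0:
            probs[i] = probability_of_engagement(int(engaged[in_win].sum()), n)

    trace = EngagementTrace(eval_times_min=eval_times,
                            probabilities_pct=probs,
                            n_trials=counts, truncated=trunc)
    t_dis = disengagement_time(trace, cfg)
    return EngagementTrace(eval_times_min=eval_times,
                           probabilities_pct=probs, n_trials=counts,
                           truncated=trunc, disengagement_min=t_dis)


def disengagement_time(trace: EngagementTrace,
                       cfg: DynamicsConfig = DynamicsConfig()) -> float | None:
    """Earliest evaluation time whose probability falls below threshold.

    Undefined (NaN) windows neither trigger nor reset the crossing rule.
    With ``min_consecutive`` > 1, that many consecutive *defined*
    sub-threshold windows are required and the first of the run is
    reported.  Returns None if the trace never crosses.
    """
    run = 0
    run_start: int | None = None
    for i, p in enumerate(trace.probabilities_pct):
        if np.isnan(p):
            continue
        if p < cfg.threshold:
            if run == 0:
                run_start = i
            run += 1
            if run >= cfg.min_consecutive:
                assert run_start is not None
                return float(trace.eval_times_min[run_start])
        else:
            run = 0
            run_start = None
    return None
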