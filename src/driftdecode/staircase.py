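"""Adaptive 1-up-2-down staircase for the fixation luminance-decrement task.

The transformed up-down rule (Levitt): an incorrect response raises the
stimulus level (a larger, easier decrement) by one step; two consecutive
correct responses lower it by one step.  At equilibrium the probability of
two consecutive correct responses is 1/2, so the staircase converges to
the intensity at which p(correct) = 1/sqrt(2) ~ 70.7%.

A simulated observer with a logistic psychometric function drives the
convergence checks; the detection task is used to titrate the decrement to
~70% correct before (or during) scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StaircaseState",
    "LogisticObserver",
    "staircase_update",
    "run_staircase",
    "StaircaseRun",
]

#: 1-up-2-down equilibrium percent correct, 100 / sqrt(2).
TARGET_PERCENT_CORRECT = 100.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class StaircaseState:
    """State of the staircase after some number of trials.

    ``level`` is the luminance-decrement intensity in arbitrary units
    (larger = easier); ``reversals`` records the level at each direction
    change.
    """

    level: float
    step: float
    consecutive_correct: int = 0
    reversals: tuple = ()
    trial_index: int = 0
    last_direction: int = 0  # +1 up (harder->easier), -1 down

    def __post_init__(self) -> None:
        if self.level <= 0:
            raise ValueError("level must be positive")
        if self.consecutive_correct not in (0, 1):
            raise ValueError("consecutive_correct must be 0 or 1")


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one trial's outcome under the 1-up-2-down rule.

    Incorrect: level increases by one step (easier) and the correct
    counter resets.  Two consecutive correct: level decreases by one step.
    A single correct response only arms the counter.  Direction changes
    append the current level to ``reversals``.
    """
    level, reversals, direction = state.level, state.reversals, state.last_direction
    counter = state.consecutive_correct
    if not correct:
        new_dir = +1
        level = level + state.step
        counter = 0
    elif counter == 0:
        return replace(
            state, consecutive_correct=1, trial_index=state.trial_index + 1
        )
    else:
        new_dir = -1
        level = max(level - state.step, state.step * 1e-3)
        counter = 0
    if direction != 0 and new_dir != direction:
        reversals = reversals + (state.level,)
    return StaircaseState(
        level=level,
        step=state.step,
        consecutive_correct=counter,
        reversals=reversals,
        trial_index=state.trial_index + 1,
        last_direction=new_dir,
    )


@dataclass(frozen=True)
class LogisticObserver:
    """Observer answering via a logistic psychometric function.

    p(correct | level) = 1 / (1 + exp(-slope * (level - threshold))).
    A very large slope approximates a step-function observer.
    """

    threshold: float
    slope: float

    def p_correct(self, level: float) -> float:
        return 1.0 / (1.0 + np.exp(-self.slope * (level - self.threshold)))

    def level_at(self, p: float) -> float:
        """Stimulus level producing probability-correct ``p``."""
        return self.threshold + np.log(p / (1.0 - p)) / self.slope


@dataclass
class StaircaseRun:
    """Trajectory of one simulated staircase run."""

    levels: np.ndarray
    correct: np.ndarray
    reversals: tuple
    asymptotic_percent_correct: float
    converged_level: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("trial\tlevel\tcorrect\n")
            for i, (l, c) in enumerate(zip(self.levels, self.correct)):
                fh.write(f"{i}\t{l:.6g}\t{int(c)}\n")


def run_staircase(
    observer: LogisticObserver,
    n_trials: int = 2000,
    seed: int = 0,
    start_level: float | None = None,
    step: float = 0.05,
) -> StaircaseRun:
    """Drive the staircase with a simulated observer.

    The asymptotic percent correct is estimated over the final half of the
    trials, after the staircase has converged near the 70.7%-correct
    level; the converged level is the mean of the last six reversals (or
    the final level if fewer occurred).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState(
        level=start_level if start_level is not None else 2.0 * observer.threshold,
        step=step,
    )
    levels = np.empty(n_trials)
    correct = np.empty(n_trials, bool)
    for i in range(n_trials):
        levels[i] = state.level
        correct[i] = rng.random() < observer.p_correct(state.level)
        state = staircase_update(state, bool(correct[i]))
    tail = slice(n_trials // 2, None)
    pc = 100.0 * correct[tail].mean()
    rev = state.reversals
    converged = float(np.mean(rev[-6:])) if len(rev) >= 1 else float(state.level)
    return StaircaseRun(
        levels=levels,
        correct=correct,
        reversals=rev,
        asymptotic_percent_correct=float(pc),
        converged_level=converged,
    )
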