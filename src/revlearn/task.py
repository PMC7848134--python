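"""Adaptive probabilistic reversal-learning task engine.

The task presents two stimuli (A/B); one is the current target. Feedback is
probabilistic: on 75% of trials (contingent trials) the agent is rewarded iff
it chose the target, on the remaining 25% the feedback is inverted. Reversals
are performance-contingent — the target flips once the agent has completed a
per-block minimum number of trials (drawn fresh each block) *and* chosen the
target on three consecutive trials — so the schedule cannot be pre-generated
and the engine must be stepped interactively.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

OPTIONS = ("A", "B")
CONDITIONS = ("control", "social", "individual")


class TaskConfigError(ValueError):
    """Raised when a TaskConfig violates its invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the reversal task.

    Defaults reproduce the study design: 75/25 feedback contingency, a
    learning criterion of 3 consecutive target choices after a per-block
    minimum of 6-10 trials, and termination at 12 reversals or 240 trials.
    """

    contingent_prob: float = 0.75
    n_reversals_max: int = 12
    n_trials_max: int = 240
    criterion_consecutive: int = 3
    min_block_trials_range: tuple[int, int] = (6, 10)
    miss_prob: float = 0.0
    blocked_contingency: bool = False  # exact 75% within each 4-trial window

    def __post_init__(self) -> None:
        lo, hi = self.min_block_trials_range
        if not (0.5 < self.contingent_prob <= 1.0):
            raise TaskConfigError("contingent_prob must be in (0.5, 1]")
        if not (0.0 <= self.miss_prob < 1.0):
            raise TaskConfigError("miss_prob must be in [0, 1)")
        if min(self.n_reversals_max, self.n_trials_max,
               self.criterion_consecutive, lo, hi) <= 0:
            raise TaskConfigError("all counts must be positive")
        if lo > hi:
            raise TaskConfigError("min_block_trials_range must be ordered")
        if lo < self.criterion_consecutive:
            raise TaskConfigError(
                "block minimum must be >= criterion_consecutive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["min_block_trials_range"] = list(self.min_block_trials_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "min_block_trials_range" in d:
            d["min_block_trials_range"] = tuple(d["min_block_trials_range"])
        return cls(**d)


@dataclass
class TaskState:
    """Mutable bookkeeping of one run (one block = one reversal epoch)."""

    current_target: str
    block_min_trials: int
    block_index: int = 0
    trials_in_block: int = 0
    consecutive_correct: int = 0
    reversals_done: int = 0
    total_trials: int = 0
    terminated: bool = False


@dataclass(frozen=True)
class TrialRecord:
    """One trial of a run. Missed trials carry no choice or feedback."""

    trial_index: int
    block_index: int
    chosen: Optional[str]
    target: str
    correct: Optional[bool]
    feedback: Optional[int]
    contingent: Optional[bool]
    missed: bool
    condition: str = "control"


def init_task(config: TaskConfig, rng: np.random.Generator) -> TaskState:
    """Start a run: draw the first block's minimum and a uniform-random target."""
    lo, hi = config.min_block_trials_range
    return TaskState(
        current_target=OPTIONS[int(rng.integers(2))],
        block_min_trials=int(rng.integers(lo, hi + 1)),
    )


def check_criterion(state: TaskState, config: TaskConfig) -> bool:
    """Learning criterion: block minimum reached and 3-in-a-row target choices.

    "Correct" here means the agent chose the current target, independent of
    the (possibly misleading) feedback actually delivered.
    """
    return (state.trials_in_block >= state.block_min_trials
            and state.consecutive_correct >= config.criterion_consecutive)


def step_task(
    state: TaskState,
    chosen: Optional[str],
    config: TaskConfig,
    rng: np.random.Generator,
) -> tuple[TrialRecord, TaskState]:
    """Play one trial in place: deliver feedback, update counters, maybe reverse.

    ``chosen`` may be None to record a missed trial (no feedback, no counter
    movement other than the trial count). Stepping a terminated state is an
    error.
    """
    if state.terminated:
        raise RuntimeError("cannot step a terminated task state")
    trial_index = state.total_trials
    state.total_trials += 1

    if chosen is None:
        record = TrialRecord(trial_index, state.block_index, None,
                             state.current_target, None, None, None, True)
    else:
        if chosen not in OPTIONS:
            raise ValueError(f"unknown option {chosen!r}")
        correct = chosen == state.current_target
        contingent = bool(rng.random() < config.contingent_prob)
        feedback = int(correct if contingent else not correct)
        record = TrialRecord(trial_index, state.block_index, chosen,
                             state.current_target, correct, feedback,
                             contingent, False)
        state.trials_in_block += 1
        state.consecutive_correct = state.consecutive_correct + 1 if correct else 0

        if check_criterion(state, config):
            state.reversals_done += 1
            if state.reversals_done >= config.n_reversals_max:
                state.terminated = True
            else:
                lo, hi = config.min_block_trials_range
                state.current_target = "B" if state.current_target == "A" else "A"
                state.block_index += 1
                state.trials_in_block = 0
                state.consecutive_correct = 0
                state.block_min_trials = int(rng.integers(lo, hi + 1))

    if state.total_trials >= config.n_trials_max:
        state.terminated = True
    return record, state
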