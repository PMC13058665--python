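"""Two-block probabilistic reward / effort learning task.

The task has two 25-trial blocks. In the *reward* block the participant
chooses between two shapes; the advantageous shape yields the high reward
(puppy image) with probability 0.75 and the low reward (dog image)
otherwise, while the effort demand is fixed at its high level (60 button
presses) on every trial. In the *effort* block the roles flip: the
advantageous shape yields the low effort demand (35 presses) with
probability 0.75, and the reward is fixed at its high level. Outcomes are
drawn i.i.d. per trial conditioned on the chosen shape.

Outcome coding is unified across blocks: ``outcome = 1`` means the
favourable event (high reward in the reward block, low effort in the
effort block), so the same learning machinery applies to both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

REWARD = "reward"
EFFORT = "effort"
BLOCKS = (REWARD, EFFORT)

ADVANTAGEOUS = "advantageous"
DISADVANTAGEOUS = "disadvantageous"
CHOICES = (ADVANTAGEOUS, DISADVANTAGEOUS)

REWARD_FIRST = "reward_first"
EFFORT_FIRST = "effort_first"
BLOCK_ORDERS = (REWARD_FIRST, EFFORT_FIRST)


class InvalidDesignError(ValueError):
    """Raised when a task configuration does not define a learnable design."""


@dataclass(frozen=True)
class TaskConfig:
    """Full design of the two-block task.

    Contingencies are the probability that the advantageous shape delivers
    the favourable outcome; they must lie strictly between 0.5 and 1 so
    that an advantageous shape exists.
    """

    reward_block_contingency: float = 0.75
    effort_block_contingency: float = 0.75
    high_effort_presses: int = 60
    low_effort_presses: int = 35
    trials_per_block: int = 25
    n_practice: int = 4
    block_order: str = REWARD_FIRST
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reward_block_contingency", "effort_block_contingency"):
            p = getattr(self, name)
            if not (0.5 < p < 1.0):
                raise InvalidDesignError(
                    f"{name}={p}: contingency must be in (0.5, 1.0); at 0.5 the "
                    "advantageous shape is undefined and at 1.0 the task is deterministic"
                )
        if not (self.high_effort_presses > self.low_effort_presses > 0):
            raise InvalidDesignError(
                "press counts must satisfy high_effort_presses > low_effort_presses > 0, "
                f"got {self.high_effort_presses} / {self.low_effort_presses}"
            )
        if self.trials_per_block <= 0:
            raise InvalidDesignError("trials_per_block must be positive")
        if self.n_practice < 0:
            raise InvalidDesignError("n_practice must be nonnegative")
        if self.block_order not in BLOCK_ORDERS:
            raise InvalidDesignError(f"unknown block_order {self.block_order!r}")

    @property
    def blocks_in_order(self) -> tuple[str, str]:
        return (REWARD, EFFORT) if self.block_order == REWARD_FIRST else (EFFORT, REWARD)

    def contingency(self, block: str) -> float:
        _check_block(block)
        return self.reward_block_contingency if block == REWARD else self.effort_block_contingency


@dataclass(frozen=True)
class TrialRecord:
    """One experimental trial.

    ``outcome`` is 1 when the favourable event occurred (high reward in the
    reward block, low effort in the effort block). ``press_speed`` (presses
    per second) is optional; pure policy simulations leave it unset.
    """

    block: str
    trial_index: int
    choice: str
    outcome: int
    reward_level: str
    effort_level: str
    required_presses: int
    press_speed: float | None = None

    def __post_init__(self) -> None:
        _check_block(self.block)
        if self.choice not in CHOICES:
            raise ValueError(f"invalid choice {self.choice!r}")
        if self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0 or 1, got {self.outcome!r}")


@dataclass
class SessionData:
    """All trials of one participant, both blocks, in presentation order."""

    participant_id: str
    config: TaskConfig
    trials: list[TrialRecord]
    practice: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = 2 * self.config.trials_per_block
        if len(self.trials) != expected:
            raise ValueError(
                f"session must contain {expected} experimental trials, got {len(self.trials)}"
            )

    def block_trials(self, block: str) -> list[TrialRecord]:
        _check_block(block)
        return [t for t in self.trials if t.block == block]


def _check_block(block: str) -> None:
    if block not in BLOCKS:
        raise ValueError(f"unknown block {block!r}; expected one of {BLOCKS}")


def build_task_config(overrides: dict | None = None, seed: int = 0) -> TaskConfig:
    """Return the default task configuration, optionally overridden.

    Defaults: 75/25 contingencies in both blocks, 60 vs 35 press effort
    levels, 25 trials per block, 4 practice trials.
    """
    overrides = dict(overrides or {})
    known = set(TaskConfig.__dataclass_fields__)
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown TaskConfig fields: {sorted(unknown)}")
    overrides.setdefault("seed", seed)
    return TaskConfig(**overrides)


def sample_outcome(
    block: str, choice: str, config: TaskConfig, rng: np.random.Generator
) -> tuple[int, str, str, int]:
    """Draw one trial outcome: ``(outcome, reward_level, effort_level, required_presses)``.

    The favourable outcome occurs with probability equal to the block
    contingency for the advantageous shape and its complement otherwise.
    The block's fixed dimension is pinned to its 100% level.
    """
    _check_block(block)
    if choice not in CHOICES:
        raise ValueError(f"invalid choice {choice!r}")
    p = config.contingency(block)
    if choice == DISADVANTAGEOUS:
        p = 1.0 - p
    o = int(rng.random() < p)
    if block == REWARD:
        reward_level = "high" if o else "low"
        effort_level = "high"  # effort fixed at 60 presses in the reward block
    else:
        reward_level = "high"  # reward fixed at the puppy image in the effort block
        effort_level = "low" if o else "high"
    presses = config.high_effort_presses if effort_level == "high" else config.low_effort_presses
    return o, reward_level, effort_level, presses


Policy = Callable[[str, Sequence[TrialRecord]], str]


def run_session(
    policy: Policy,
    config: TaskConfig,
    rng: np.random.Generator,
    participant_id: str = "sim",
) -> SessionData:
    """Simulate a full session (both blocks) under an arbitrary choice policy.

    ``policy(block, history)`` receives the trials completed so far in the
    current block and returns ``"advantageous"`` or ``"disadvantageous"``.
    Practice trials (first block's mechanics) are generated and stored
    separately; they never enter analyses.
    """
    first_block = config.blocks_in_order[0]
    practice: list[TrialRecord] = []
    for i in range(config.n_practice):
        choice = ADVANTAGEOUS if rng.random() < 0.5 else DISADVANTAGEOUS
        o, rl, el, presses = sample_outcome(first_block, choice, config, rng)
        practice.append(TrialRecord(first_block, i, choice, o, rl, el, presses))

    trials: list[TrialRecord] = []
    for block in config.blocks_in_order:
        history: list[TrialRecord] = []
        for i in range(config.trials_per_block):
            choice = policy(block, history)
            if choice not in CHOICES:
                raise ValueError(f"policy returned invalid choice {choice!r}")
            o, rl, el, presses = sample_outcome(block, choice, config, rng)
            rec = TrialRecord(block, i, choice, o, rl, el, presses)
            history.append(rec)
            trials.append(rec)
    return SessionData(participant_id, config, trials, practice)


def learning_accuracy(
    session: SessionData, block: str, bin_size: int = 5
) -> tuple[float, np.ndarray]:
    """Proportion of advantageous choices in a block, overall and per bin.

    Returns ``(overall, curve)`` where ``curve[i]`` is the advantageous
    fraction within consecutive bins of ``bin_size`` trials. A final
    partial bin is allowed (its fraction uses the actual bin length).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    trials = session.block_trials(block)
    if not trials:
        raise ValueError(f"session has no trials in block {block!r}")
    hits = np.array([t.choice == ADVANTAGEOUS for t in trials], dtype=float)
    overall = float(hits.mean())
    curve = np.array(
        [hits[i : i + bin_size].mean() for i in range(0, len(hits), bin_size)]
    )
    return overall, curve


def with_press_speeds(session: SessionData, speeds: Sequence[float]) -> SessionData:
    """Return a copy of the session with per-trial press speeds attached."""
    if len(speeds) != len(session.trials):
        raise ValueError("need one press speed per experimental trial")
    trials = [replace(t, press_speed=float(s)) for t, s in zip(session.trials, speeds)]
    return SessionData(session.participant_id, session.config, trials, session.practice)
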