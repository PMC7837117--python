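"""Stochastic environments for the two-step task and the probabilistic reversal-learning task.

The two-step task: a first-step choice between *top* and *bottom* pokes leads
probabilistically (common 0.8 / rare 0.2) to a *left-active* or *right-active*
second-step state where a probabilistic water reward is delivered.  Reward and
transition probabilities are block structured; block transitions are triggered
by the subject's own behaviour (an exponential moving average of correct
choices crossing a threshold) in non-neutral blocks, and by a per-trial hazard
in neutral blocks.

Integer codings used throughout the package:

* choice: 1 = top, 0 = bottom (reversal-learning variant: 1 = left, 0 = right)
* second_step: 1 = left, 0 = right
* transition_state: 0 = "A" (top->left / bottom->right common), 1 = "B"
* reward_state: 0 = left_good, 1 = neutral, 2 = right_good
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "TaskConfig",
    "BlockState",
    "Session",
    "make_initial_block",
    "correct_choice",
    "step_trial",
    "step_trial_reversal",
    "update_block",
    "sample_block_transition",
    "stim_schedule",
    "neutral_block_lengths",
    "simulate_random_session",
]

# String labels used for (de)serialization.
CHOICE_LABELS = {1: "top", 0: "bottom"}
SECOND_STEP_LABELS = {1: "left", 0: "right"}
TRANSITION_LABELS = {0: "A", 1: "B"}
REWARD_LABELS = {0: "left_good", 1: "neutral", 2: "right_good"}


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the block-structured task environment.

    ``reward_probs`` is the (good, neutral, bad) reward-probability triple.
    The default values are the final training stage of the two-step task
    (0.8 / 0.2 transition probabilities, 0.8 / 0.4 / 0.2 reward probabilities).
    """

    common_prob: float = 0.8
    reward_probs: tuple[float, float, float] = (0.8, 0.4, 0.2)
    ema_tau: float = 8.0
    threshold: float = 0.75
    post_threshold_delay: int = 20
    neutral_min_trials: int = 40
    neutral_hazard: float = 0.1
    fixed_transitions: bool = False
    variant: str = "two_step"

    def __post_init__(self) -> None:
        good, neutral, bad = self.reward_probs
        if not (0.0 <= bad < neutral < good <= 1.0):
            raise ValueError("reward_probs must satisfy good > neutral > bad in [0, 1]")
        if not 0.0 <= self.common_prob <= 1.0:
            raise ValueError("common_prob must be in [0, 1]")
        if not 0.0 <= self.neutral_hazard <= 1.0:
            raise ValueError("neutral_hazard must be in [0, 1]")
        if self.ema_tau <= 0:
            raise ValueError("ema_tau must be positive")
        if self.variant not in ("two_step", "reversal_learning"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @classmethod
    def reversal_learning(cls) -> "TaskConfig":
        """Configuration of the probabilistic reversal-learning task variant.

        Reward probabilities 0.75 / 0.5 / 0.25, behavioural threshold crossing
        followed by a 10-trial delay, neutral-block hazard 0.1 after trial 15
        (mean neutral block length 25 trials).
        """
        return cls(
            reward_probs=(0.75, 0.5, 0.25),
            post_threshold_delay=10,
            neutral_min_trials=15,
            fixed_transitions=True,
            variant="reversal_learning",
        )


@dataclass(frozen=True)
class BlockState:
    """State of the reward/transition-probability block and its trigger logic.

    ``ema_correct`` is the exponential moving average of the correct-choice
    indicator (initialised at 0.5 at block start); ``threshold_crossed_trial``
    records the trial within the block on which the EMA first exceeded the
    threshold (None before crossing, and always None in neutral blocks, where
    no correct choice exists and only the hazard applies).
    """

    transition_state: int = 0
    reward_state: int = 0
    trials_in_block: int = 0
    ema_correct: float = 0.5
    threshold_crossed_trial: Optional[int] = None

    def __post_init__(self) -> None:
        if self.transition_state not in (0, 1):
            raise ValueError("transition_state must be 0 or 1")
        if self.reward_state not in (0, 1, 2):
            raise ValueError("reward_state must be 0, 1 or 2")
        if not 0.0 <= self.ema_correct <= 1.0:
            raise ValueError("ema_correct must be in [0, 1]")

    @property
    def is_neutral(self) -> bool:
        return self.reward_state == 1


def make_initial_block(config: TaskConfig, rng: np.random.Generator) -> BlockState:
    """Draw a uniformly random starting block (used at the start of a chain of
    sessions; chained sessions carry the previous session's final block)."""
    ts = 0 if config.fixed_transitions else int(rng.integers(2))
    rs = int(rng.choice([0, 1, 2]))
    return BlockState(transition_state=ts, reward_state=rs)


def correct_choice(block: BlockState, config: TaskConfig) -> Optional[int]:
    """First-step action with the higher expected reward, or None in neutral blocks.

    In the two-step task the correct action is the one whose *common*
    transition reaches the good side; in the reversal-learning task it is the
    good side itself.
    """
    if block.is_neutral:
        return None
    good_state = 1 if block.reward_state == 0 else 0  # 1 = left
    if config.variant == "reversal_learning":
        return good_state
    # transition_state 0: top(1)->left(1); transition_state 1: top(1)->right(0)
    return good_state if block.transition_state == 0 else 1 - good_state


def _reward_prob(block: BlockState, state: int, config: TaskConfig) -> float:
    """Reward probability at second-step state ``state`` (1 = left) under the block."""
    good, neutral, bad = config.reward_probs
    if block.reward_state == 1:
        return neutral
    good_state = 1 if block.reward_state == 0 else 0
    return good if state == good_state else bad


def step_trial(
    block: BlockState, choice: int, config: TaskConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Run one two-step trial: draw the second-step state and the outcome.

    Returns ``(second_step, outcome)`` where the second step is the common
    destination of ``choice`` with probability ``config.common_prob``.
    """
    if choice not in (0, 1):
        raise ValueError(f"invalid first-step choice {choice!r}; expected 0 (bottom) or 1 (top)")
    common_dest = choice if block.transition_state == 0 else 1 - choice
    if rng.random() < config.common_prob:
        second_step = common_dest
    else:
        second_step = 1 - common_dest
    outcome = int(rng.random() < _reward_prob(block, second_step, config))
    return second_step, outcome


def step_trial_reversal(
    block: BlockState, choice: int, config: TaskConfig, rng: np.random.Generator
) -> int:
    """Run one reversal-learning trial: reward drawn at the chosen port's probability."""
    if choice not in (0, 1):
        raise ValueError(f"invalid choice {choice!r}; expected 0 (right) or 1 (left)")
    return int(rng.random() < _reward_prob(block, choice, config))


def update_block(
    block: BlockState,
    choice: int,
    outcome: int,
    config: TaskConfig,
    rng: np.random.Generator,
) -> tuple[BlockState, bool]:
    """Advance the block-trigger logic by one completed trial.

    In non-neutral blocks the EMA of the correct-choice indicator is updated
    (``ema += (I_correct - ema) / tau``) and a block transition fires exactly
    ``post_threshold_delay`` trials after the EMA first exceeds the threshold.
    In neutral blocks a transition fires with probability ``neutral_hazard``
    on each trial after the ``neutral_min_trials``-th.

    Returns ``(new_block, transitioned)``.
    """
    n = block.trials_in_block + 1
    if block.is_neutral:
        new = replace(block, trials_in_block=n)
        if n > config.neutral_min_trials and rng.random() < config.neutral_hazard:
            return sample_block_transition(new, config, rng), True
        return new, False

    corr = correct_choice(block, config)
    ema = block.ema_correct + ((1.0 if choice == corr else 0.0) - block.ema_correct) / config.ema_tau
    crossed = block.threshold_crossed_trial
    if crossed is None and ema > config.threshold:
        crossed = n
    new = replace(block, trials_in_block=n, ema_correct=ema, threshold_crossed_trial=crossed)
    if crossed is not None and n >= crossed + config.post_threshold_delay:
        return sample_block_transition(new, config, rng), True
    return new, False


def sample_block_transition(
    block: BlockState, config: TaskConfig, rng: np.random.Generator
) -> BlockState:
    """Draw the destination block of a triggered transition.

    From non-neutral blocks each of the four destinations has probability 0.25:
    reward-probability reversal, transition-probability reversal, or one of the
    two neutral blocks.  From neutral blocks the reward probabilities change to
    one of the two non-neutral states (0.5 each) with the transition
    probabilities unchanged.  With ``fixed_transitions`` the 25% transition-
    reversal mass is reassigned to the reward reversal and the transition state
    never changes.
    """
    ts, rs = block.transition_state, block.reward_state
    if block.is_neutral:
        rs = int(rng.choice([0, 2]))
    elif config.fixed_transitions:
        # 0.5 reward reversal, 0.5 neutral (transition-reversal mass folded in).
        if rng.random() < 0.5:
            rs = 2 - rs
        else:
            rs = 1
    else:
        u = rng.random()
        if u < 0.25:
            rs = 2 - rs  # reward-probability reversal
        elif u < 0.5:
            ts = 1 - ts  # transition-probability reversal
        elif u < 0.75:
            rs = 1  # neutral, same transition state
        else:
            rs, ts = 1, 1 - ts  # neutral, other transition state
    return BlockState(transition_state=ts, reward_state=rs)


def stim_schedule(
    n_trials: int,
    rng: np.random.Generator,
    stim_prob: float = 0.25,
    refractory: int = 2,
) -> np.ndarray:
    """Optogenetic stimulation flags: after each stimulated trial a fixed number
    of forced non-stimulated trials, then stimulation with probability
    ``stim_prob`` on each subsequent trial (long-run stimulated fraction 1/6
    at the defaults)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    stim = np.zeros(n_trials, dtype=np.int8)
    cooldown = 0
    for t in range(n_trials):
        if cooldown > 0:
            cooldown -= 1
        elif rng.random() < stim_prob:
            stim[t] = 1
            cooldown = refractory
    return stim


def neutral_block_lengths(
    config: TaskConfig,
    n_blocks: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Lengths of ``n_blocks`` simulated neutral blocks under the block logic
    (hazard applied per trial after the configured minimum)."""
    lengths = np.empty(n_blocks, dtype=np.int64)
    for k in range(n_blocks):
        block = BlockState(transition_state=0, reward_state=1)
        n = 0
        while True:
            n += 1
            block, transitioned = update_block(block, 0, 0, config, rng)
            if transitioned:
                break
        lengths[k] = n
    return lengths


def simulate_random_session(
    config: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
    subject_id: str = "sub0",
    session_id: str = "ses0",
    init_block: Optional[BlockState] = None,
    rng_seed: Optional[int] = None,
) -> "Session":
    """Simulate a session under a uniform-random choice policy.

    Exercises the environment without an agent (reversal-learning sessions
    are recorded with ``second_step == choice`` and transition state 0, since
    the variant has no first-step/second-step distinction).
    """
    block = init_block if init_block is not None else make_initial_block(config, rng)
    choice = np.empty(n_trials, dtype=np.int8)
    second = np.empty(n_trials, dtype=np.int8)
    outcome = np.empty(n_trials, dtype=np.int8)
    ts = np.empty(n_trials, dtype=np.int8)
    rs = np.empty(n_trials, dtype=np.int8)
    block_idx = np.empty(n_trials, dtype=np.int16)
    b = 0
    for t in range(n_trials):
        c = int(rng.integers(2))
        if config.variant == "reversal_learning":
            s, r = c, step_trial_reversal(block, c, config, rng)
        else:
            s, r = step_trial(block, c, config, rng)
        choice[t], second[t], outcome[t] = c, s, r
        ts[t], rs[t], block_idx[t] = block.transition_state, block.reward_state, b
        block, transitioned = update_block(block, c, r, config, rng)
        if transitioned:
            b += 1
    return Session(choice=choice, second_step=second, outcome=outcome,
                   transition_state=ts, reward_state=rs, block_index=block_idx,
                   subject_id=subject_id, session_id=session_id,
                   rng_seed=rng_seed, config=config, final_block=block)


@dataclass
class Session:
    """Per-trial behavioural record of one session.

    All arrays have equal length.  ``transition_state`` / ``reward_state`` are
    the block labels in force on each trial, ``block_index`` counts blocks
    within the session, and ``stim`` flags trials whose choice was made under
    optogenetic stimulation (light on from the previous trial's outcome to
    this trial's choice); ``stim`` may be None for non-opto sessions.
    """

    choice: np.ndarray
    second_step: np.ndarray
    outcome: np.ndarray
    transition_state: np.ndarray
    reward_state: np.ndarray
    block_index: np.ndarray
    stim: Optional[np.ndarray] = None
    subject_id: str = "sub0"
    session_id: str = "ses0"
    rng_seed: Optional[int] = None
    config: TaskConfig = field(default_factory=TaskConfig)
    true_params: Optional[dict] = None  # generating parameters, for recovery tests
    true_params_transformed: Optional[dict] = None
    final_block: Optional[BlockState] = None  # carried over when chaining sessions

    def __post_init__(self) -> None:
        arrays = [self.choice, self.second_step, self.outcome,
                  self.transition_state, self.reward_state, self.block_index]
        if self.stim is not None:
            arrays.append(self.stim)
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("all per-trial arrays must have equal length")
        for name in ("choice", "second_step", "outcome"):
            a = getattr(self, name)
            if not np.isin(a, [0, 1]).all():
                raise ValueError(f"{name} must be binary (0/1)")
        if not np.isin(self.reward_state, [0, 1, 2]).all():
            raise ValueError("reward_state must be in {0, 1, 2}")

    @property
    def n_trials(self) -> int:
        return len(self.choice)

    @property
    def common_transition(self) -> np.ndarray:
        """Boolean array: did the trial's transition match the commonly
        rewarded mapping of the block it occurred in?"""
        same = self.choice == self.second_step
        return np.where(self.transition_state == 0, same, ~same)

    @property
    def correct_choice_per_trial(self) -> np.ndarray:
        """Correct first-step action per trial (-1 in neutral blocks)."""
        good_state = np.where(self.reward_state == 0, 1, 0)
        corr = np.where(self.transition_state == 0, good_state, 1 - good_state)
        return np.where(self.reward_state == 1, -1, corr).astype(np.int8)
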