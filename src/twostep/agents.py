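"""Reinforcement-learning model family for the two-step task.

A single 14-parameter engine implements a mixture of strategies: model-free
action values with eligibility traces and value forgetting, motor-level
model-free values, model-based values computed from learned action->state
transition probabilities, choice/rotational biases and single- or multi-trial
perseveration at both the choice and motor level.  Component models
(model-free only, model-based only) are the same engine with parameter masks.

The module exposes both directions: :func:`simulate_agent` generates choices
in closed loop with the task environment, and :func:`session_loglik` scores an
observed session under given parameters (the quantity maximised by the
hierarchical fitting machinery in :mod:`twostep.hierfit`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import task as _task
from ._rl_core import rl_loglik
from .task import BlockState, Session, TaskConfig

__all__ = [
    "PARAM_NAMES",
    "PARAM_TRANSFORMS",
    "MODELS",
    "ModelSpec",
    "AgentParams",
    "AgentState",
    "init_state",
    "compute_net_values",
    "choice_probabilities",
    "update_state",
    "session_loglik",
    "simulate_agent",
]

#: Canonical parameter order used by every vectorised interface.
PARAM_NAMES = (
    "alpha_Q", "f_Q", "lam", "alpha_T", "f_T", "alpha_c", "alpha_m",
    "G_mf", "G_mo", "G_mb", "B_c", "B_r", "P_c", "P_m",
)

_RATES = ("alpha_Q", "f_Q", "lam", "alpha_T", "f_T", "alpha_c", "alpha_m")
_WEIGHTS = ("G_mf", "G_mo", "G_mb")

#: Constraint-enforcing transform per parameter: unit-interval rates are
#: logit-transformed, positive weights log-transformed, biases unconstrained.
PARAM_TRANSFORMS = {
    name: ("logit" if name in _RATES else "log" if name in _WEIGHTS else "identity")
    for name in PARAM_NAMES
}


@dataclass(frozen=True)
class AgentParams:
    """Natural-space parameters of the RL model.

    Learning/forgetting rates lie in (0, 1), value weights ``G_*`` are
    positive, biases and perseveration strengths are unbounded.
    """

    alpha_Q: float = 0.5
    f_Q: float = 0.1
    lam: float = 0.7
    alpha_T: float = 0.5
    f_T: float = 0.1
    alpha_c: float = 0.3
    alpha_m: float = 0.3
    G_mf: float = 1.0
    G_mo: float = 1.0
    G_mb: float = 1.0
    B_c: float = 0.0
    B_r: float = 0.0
    P_c: float = 0.0
    P_m: float = 0.0

    def __post_init__(self) -> None:
        for name in _RATES:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie strictly in (0, 1)")
        for name in _WEIGHTS:
            v = getattr(self, name)
            if v < 0.0:
                raise ValueError(f"{name}={v} must be non-negative")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "AgentParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, vec))))

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class ModelSpec:
    """A component model: which parameters are free, and the fixed values of
    the rest.  Fixed rates are set to inert mid-range values; they only touch
    variables whose weight is fixed at zero."""

    name: str
    free: tuple[str, ...]
    fixed: dict = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def transforms(self) -> tuple[str, ...]:
        return tuple(PARAM_TRANSFORMS[n] for n in self.free)

    def full_params(self, free_values: Sequence[float]) -> AgentParams:
        d = dict(self.fixed)
        d.update(zip(self.free, map(float, free_values)))
        return AgentParams(**d)

    def full_vector(self, free_values: Sequence[float]) -> np.ndarray:
        return self.full_params(free_values).to_vector()

    def free_vector(self, params: AgentParams) -> np.ndarray:
        return np.array([getattr(params, n) for n in self.free], dtype=float)


_INERT = {"alpha_T": 0.5, "f_T": 0.5, "alpha_m": 0.5, "lam": 0.5, "alpha_c": 0.5}

#: Model library: "mf" is the model-free agent with eligibility traces, value
#: forgetting and multi-trial perseveration; "mb" the model-based agent with
#: value and transition-probability forgetting; "best" the full mixture.
MODELS = {
    "mf": ModelSpec(
        name="mf",
        free=("alpha_Q", "f_Q", "lam", "alpha_c", "G_mf", "B_c", "P_c"),
        fixed={"G_mo": 0.0, "G_mb": 0.0, "B_r": 0.0, "P_m": 0.0,
               "alpha_T": _INERT["alpha_T"], "f_T": _INERT["f_T"],
               "alpha_m": _INERT["alpha_m"]},
    ),
    "mb": ModelSpec(
        name="mb",
        free=("alpha_Q", "f_Q", "alpha_T", "f_T", "alpha_c", "G_mb", "B_c", "P_c"),
        fixed={"G_mf": 0.0, "G_mo": 0.0, "B_r": 0.0, "P_m": 0.0,
               "lam": _INERT["lam"], "alpha_m": _INERT["alpha_m"]},
    ),
    "best": ModelSpec(name="best", free=PARAM_NAMES, fixed={}),
}


@dataclass
class AgentState:
    """Evolving latent variables of the agent.

    ``p_left[c]`` is the estimated probability that choice ``c`` leads to the
    left-active state; its complement is the right-state probability, so the
    two transition estimates always sum to one.  ``s_prev`` is the previous
    trial's second-step state (-1 on the first trial of a session).
    """

    q_mf: np.ndarray
    v: np.ndarray
    p_left: np.ndarray
    q_mo: np.ndarray
    c_bar: float
    m_bar: np.ndarray
    s_prev: int = -1


def init_state(params: AgentParams) -> AgentState:
    """Fresh agent state: values and transition estimates at 0.5 (the
    reward-scale midpoint and the forgetting fixed point), histories at 0."""
    return AgentState(
        q_mf=np.full(2, 0.5),
        v=np.full(2, 0.5),
        p_left=np.full(2, 0.5),
        q_mo=np.full((2, 2), 0.5),
        c_bar=0.0,
        m_bar=np.zeros(2),
        s_prev=-1,
    )


def compute_net_values(
    state: AgentState,
    params: AgentParams,
    s_prev: Optional[int] = None,
) -> tuple[float, float]:
    """Net action values ``(Q_net(top), Q_net(bottom))``.

    The model-based value is Q_mb(c) = sum_s P(s|c) V(s).  The bias and
    perseveration offset X applies to the top action only.  Terms that
    reference the previous trial's second-step state (motor values,
    rotational bias, motor perseveration) are omitted on the first trial.
    """
    if s_prev is None:
        s_prev = state.s_prev
    pl = state.p_left
    v = state.v
    q_mb_top = pl[1] * v[1] + (1.0 - pl[1]) * v[0]
    q_mb_bot = pl[0] * v[1] + (1.0 - pl[0]) * v[0]
    g_mb = params.G_mb
    q_top = params.G_mf * state.q_mf[1] + g_mb * q_mb_top + params.B_c + params.P_c * state.c_bar
    q_bot = params.G_mf * state.q_mf[0] + g_mb * q_mb_bot
    if s_prev >= 0:
        q_top += (params.G_mo * state.q_mo[1, s_prev]
                  + params.B_r * (s_prev - 0.5)
                  + params.P_m * state.m_bar[s_prev])
        q_bot += params.G_mo * state.q_mo[0, s_prev]
    return q_top, q_bot


def choice_probabilities(q_net: Sequence[float]) -> np.ndarray:
    """Softmax over net action values, in the same order as the input (so
    ``(Q_net(top), Q_net(bottom))`` yields ``[P(top), P(bottom)]``).
    Max-subtracted for overflow safety."""
    q = np.asarray(q_net, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite net action values")
    e = np.exp(q - q.max())
    return e / e.sum()


def update_state(state: AgentState, c: int, s: int, r: int, params: AgentParams,
                 alpha_t_scale: float = 1.0) -> AgentState:
    """Apply one trial's learning updates in place (and return the state).

    Order matters only for the second-step value: the model-free and motor
    targets use V(s) as it was before its own update.  ``alpha_t_scale``
    attenuates the transition-probability learning rate for this trial's
    observation (used to implant optogenetic effects in synthetic data: the
    illuminated outcome-to-next-choice window suppresses consolidation of
    the observed transition).
    """
    if c not in (0, 1) or s not in (0, 1) or r not in (0, 1):
        raise ValueError("c, s and r must each be 0 or 1")
    a_q, f_q, lam = params.alpha_Q, params.f_Q, params.lam
    v_s = state.v[s]
    target = lam * r + (1.0 - lam) * v_s
    state.q_mf[c] = (1.0 - a_q) * state.q_mf[c] + a_q * target
    state.v[s] = (1.0 - a_q) * v_s + a_q * r
    state.q_mf[1 - c] *= (1.0 - f_q)
    state.v[1 - s] *= (1.0 - f_q)

    a_t, f_t = params.alpha_T * alpha_t_scale, params.f_T
    if s == 1:
        state.p_left[c] = (1.0 - a_t) * state.p_left[c] + a_t
    else:
        state.p_left[c] = (1.0 - a_t) * state.p_left[c]
    state.p_left[1 - c] = (1.0 - f_t) * state.p_left[1 - c] + 0.5 * f_t

    if state.s_prev >= 0:
        for cc in range(2):
            for ss in range(2):
                if cc == c and ss == state.s_prev:
                    state.q_mo[cc, ss] = (1.0 - a_q) * state.q_mo[cc, ss] + a_q * target
                else:
                    state.q_mo[cc, ss] *= (1.0 - f_q)

    state.c_bar = (1.0 - params.alpha_c) * state.c_bar + params.alpha_c * (c - 0.5)
    if state.s_prev >= 0:
        sp = state.s_prev
        state.m_bar[sp] = (1.0 - params.alpha_m) * state.m_bar[sp] + params.alpha_m * (c - 0.5)

    state.s_prev = s
    return state


def session_loglik(session: Session, params: AgentParams) -> float:
    """Log-likelihood of the session's observed choices under the model.

    Deterministic given the session and parameters: the agent state is evolved
    from the observed (choice, second step, outcome) sequence and each choice
    is scored under the softmax.
    """
    if session.n_trials == 0:
        raise ValueError("empty session")
    return float(rl_loglik(
        params.to_vector(),
        np.ascontiguousarray(session.choice, dtype=np.int64),
        np.ascontiguousarray(session.second_step, dtype=np.int64),
        np.ascontiguousarray(session.outcome, dtype=np.int64),
    ))


def simulate_agent(
    params: AgentParams,
    task_config: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
    subject_id: str = "sub0",
    session_id: str = "ses0",
    init_block: Optional[BlockState] = None,
    stim: Optional[np.ndarray] = None,
    stim_alpha_t_scale: float = 1.0,
    rng_seed: Optional[int] = None,
) -> Session:
    """Simulate a session in closed loop with the two-step task environment.

    ``stim[t] = 1`` marks a trial whose choice was made under optogenetic
    stimulation (light on from the previous trial's outcome through this
    trial's choice).  The synthetic manipulation attenuates the
    transition-probability update performed during the illuminated window —
    the previous trial's observed transition is learned with
    ``alpha_T * stim_alpha_t_scale`` — reducing the influence of that
    transition on the stimulated choice.  ``init_block`` carries the block
    state over from a previous session when chaining; the final block is
    stored on the returned session.
    """
    if task_config.variant != "two_step":
        raise ValueError("simulate_agent runs the two_step variant")
    block = init_block if init_block is not None else _task.make_initial_block(task_config, rng)
    block = replace(block)  # do not mutate the caller's chain state
    state = init_state(params)

    choice = np.empty(n_trials, dtype=np.int8)
    second = np.empty(n_trials, dtype=np.int8)
    outcome = np.empty(n_trials, dtype=np.int8)
    trans_state = np.empty(n_trials, dtype=np.int8)
    rew_state = np.empty(n_trials, dtype=np.int8)
    block_idx = np.empty(n_trials, dtype=np.int16)

    b_idx = 0
    for t in range(n_trials):
        q_net = compute_net_values(state, params)
        d = q_net[0] - q_net[1]  # Q_net(top) - Q_net(bottom)
        p_top = 1.0 / (1.0 + math.exp(-d)) if d > -35 else 0.0
        c = int(rng.random() < p_top)
        s, r = _task.step_trial(block, c, task_config, rng)

        choice[t] = c
        second[t] = s
        outcome[t] = r
        trans_state[t] = block.transition_state
        rew_state[t] = block.reward_state
        block_idx[t] = b_idx

        # light during this trial's outcome -> next choice = next trial's stim flag
        lit = stim is not None and t + 1 < n_trials and stim[t + 1]
        update_state(state, c, s, r, params,
                     alpha_t_scale=stim_alpha_t_scale if lit else 1.0)
        block, transitioned = _task.update_block(block, c, r, task_config, rng)
        if transitioned:
            b_idx += 1

    return Session(
        choice=choice, second_step=second, outcome=outcome,
        transition_state=trans_state, reward_state=rew_state,
        block_index=block_idx,
        stim=None if stim is None else np.asarray(stim, dtype=np.int8),
        subject_id=subject_id, session_id=session_id, rng_seed=rng_seed,
        config=task_config,
        true_params={n: getattr(params, n) for n in PARAM_NAMES},
        final_block=block,
    )
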