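"""Synthetic behavioural, optogenetic and neural datasets.

Generators produce data with the statistical structure the analysis modules
assume: block-structured two-step behaviour from a mixture-of-strategies RL
agent whose per-session parameters are drawn from a population Gaussian in
transformed space; 1-in-6 stimulation schedules with an optional planted
effect that attenuates the model-based weight on stimulated trials; and
sparse event-like neural activity (Poisson counts at the 10 Hz frame rate,
~0.12 Hz mean event rate by default) with planted tuning kernels locked to
trial events — including orthogonal pre- and post-outcome second-step
populations and outcome cells gated by the second-step state.

The default population parameter values are plausible mid-range picks used
to exercise the pipeline; they are not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .agents import MODELS, PARAM_NAMES, PARAM_TRANSFORMS, simulate_agent
from .hierfit import transform_values, untransform_values
from .neural import NeuralSession
from .task import Session, TaskConfig, make_initial_block, stim_schedule

__all__ = [
    "DEFAULT_POPULATION_MEANS",
    "DEFAULT_POPULATION_SD",
    "CohortSpec",
    "NeuralSpec",
    "population_prior_vectors",
    "generate_behavior_cohort",
    "generate_opto_cohort",
    "generate_neural_session",
    "generate_neural_cohort",
]

#: Natural-space population means of the full model (mid-range defaults).
DEFAULT_POPULATION_MEANS = {
    "alpha_Q": 0.5, "f_Q": 0.15, "lam": 0.7, "alpha_T": 0.5, "f_T": 0.15,
    "alpha_c": 0.25, "alpha_m": 0.25,
    "G_mf": 2.0, "G_mo": 1.5, "G_mb": 3.0,
    "B_c": 0.1, "B_r": 0.2, "P_c": 1.0, "P_m": 1.0,
}

#: Transformed-space population SDs (logit/log scale for rates/weights).
DEFAULT_POPULATION_SD = {
    name: (0.2 if PARAM_TRANSFORMS[name] == "identity" else 0.4)
    for name in PARAM_NAMES
}


def population_prior_vectors(
    model: str = "best",
    means: Optional[dict] = None,
    sds: Optional[dict] = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Transformed-space (mu, sd, names) of the generating population for a
    model mask's free parameters."""
    spec = MODELS[model]
    means = {**DEFAULT_POPULATION_MEANS, **(means or {})}
    sds = {**DEFAULT_POPULATION_SD, **(sds or {})}
    mu = transform_values([means[n] for n in spec.free], spec.transforms)
    sd = np.array([sds[n] for n in spec.free], dtype=float)
    return mu, sd, spec.free


@dataclass
class CohortSpec:
    """Conditions of a synthetic behavioural cohort.

    Per-session parameters are drawn from N(mu, sd^2) in transformed space
    for the free parameters of ``model``.  ``stim_effect`` in [0, 1]
    attenuates the transition-probability update made during the illuminated
    outcome-to-choice window (learning rate scaled by 1 - effect), reducing
    the influence of the observed transition on the stimulated choice.
    """

    n_subjects: int = 10
    sessions_per_subject: int = 1
    trials_per_session: int = 500
    model: str = "best"
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    task: TaskConfig = field(default_factory=TaskConfig)
    stim: bool = False
    stim_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.trials_per_session < 50:
            raise ValueError("trials_per_session must be >= 50")
        if not 0.0 <= self.stim_effect <= 1.0:
            raise ValueError("stim_effect must be in [0, 1]")
        if any(v < 0 for v in self.sds.values()):
            raise ValueError("population SDs must be non-negative")


def generate_behavior_cohort(spec: CohortSpec, rng: np.random.Generator) -> list[Session]:
    """Simulate a cohort of sessions from the population model.

    Each subject's sessions are chained (the block state carries over); every
    session stores its generating parameters in ``true_params`` and its
    transformed free vector in ``true_params_transformed`` for recovery tests.
    """
    mu, sd, names = population_prior_vectors(spec.model, spec.means, spec.sds)
    model = MODELS[spec.model]
    sessions = []
    for i in range(spec.n_subjects):
        block = make_initial_block(spec.task, rng)
        for j in range(spec.sessions_per_subject):
            h = mu + sd * rng.standard_normal(len(names))
            params = model.full_params(untransform_values(h, model.transforms))
            stim = (stim_schedule(spec.trials_per_session, rng) if spec.stim else None)
            s = simulate_agent(
                params, spec.task, spec.trials_per_session, rng,
                subject_id=f"sub{i:03d}", session_id=f"ses{j:03d}",
                init_block=block, stim=stim,
                stim_alpha_t_scale=1.0 - spec.stim_effect)
            s.true_params_transformed = dict(zip(names, h))
            block = s.final_block
            sessions.append(s)
    return sessions


def generate_opto_cohort(spec: CohortSpec, rng: np.random.Generator) -> list[Session]:
    """Behavioural cohort with 1-in-6 stimulation schedules and the planted
    optogenetic effect of ``spec.stim_effect`` (0 for a control group)."""
    spec = CohortSpec(**{**spec.__dict__, "stim": True})
    return generate_behavior_cohort(spec, rng)


# ---------------------------------------------------------------------------
# Neural data

@dataclass
class NeuralSpec:
    """Forward model for synthetic deconvolved activity.

    Tuned neurons add Gaussian rate bumps (SD ``kernel_sd`` s, integral
    ``amplitude`` events) locked to trial events on trials matching their
    preference; the remaining rate is untuned baseline, set so the
    population-mean event rate matches ``mean_rate`` (when the tuning mass
    allows).  Fractions assign neurons to: choice cells (peri-choice),
    pre-outcome and post-outcome second-step cells (orthogonal populations),
    and outcome cells gated by second-step state (left-port and right-port
    outcome cells; reward coding specific to where it was obtained).
    """

    n_neurons: int = 60
    mean_rate: float = 0.12            # Hz, population mean
    frame_rate: float = 10.0
    tuned_fractions: dict = field(default_factory=lambda: {
        "choice": 0.15, "second_step_pre": 0.15, "second_step_post": 0.15,
        "outcome_left": 0.1, "outcome_right": 0.1})
    amplitude: float = 0.25            # events per preferred trial
    kernel_sd: float = 0.2             # s
    interval_range: tuple[float, float] = (0.4, 1.0)   # choice->outcome s
    iti: float = 2.5                   # outcome -> next choice, s
    min_baseline: float = 0.005        # Hz floor for the untuned rate

    def __post_init__(self) -> None:
        if sum(self.tuned_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("tuned fractions must sum to <= 1")
        if self.mean_rate < 0 or self.amplitude < 0:
            raise ValueError("rates and amplitudes must be non-negative")


def _assign_tuning(spec: NeuralSpec, rng: np.random.Generator) -> list[tuple[str, int]]:
    """(tuning kind, preferred value) per neuron; kind 'none' for untuned."""
    kinds: list[tuple[str, int]] = []
    for kind, frac in spec.tuned_fractions.items():
        n = int(round(frac * spec.n_neurons))
        kinds += [(kind, k % 2) for k in range(n)]
    kinds += [("none", 0)] * (spec.n_neurons - len(kinds))
    order = rng.permutation(len(kinds))
    return [kinds[i] for i in order]


def generate_neural_session(
    behavior: Session,
    spec: NeuralSpec,
    rng: np.random.Generator,
) -> NeuralSession:
    """Sparse event-like activity for one behavioural session.

    Per-trial event times are jittered (uniform choice-to-outcome interval);
    neurons emit Poisson counts per frame at baseline plus planted tuning
    kernels.  Preference gating: choice cells fire peri-choice on trials with
    their preferred choice; second-step cells fire mid-trial (pre) or 250 ms
    after outcome (post) on trials reaching their preferred state; outcome
    cells fire post-outcome on trials reaching their port with their
    preferred reward value.
    """
    n_trials = behavior.n_trials
    lo, hi = spec.interval_range
    intervals = rng.uniform(lo, hi, size=n_trials)
    choice_times = np.empty(n_trials)
    t = 2.0
    for i in range(n_trials):
        choice_times[i] = t
        t = t + intervals[i] + spec.iti
    outcome_times = choice_times + intervals
    n_frames = int(np.ceil((outcome_times[-1] + 2.0) * spec.frame_rate))
    frame_t = np.arange(n_frames) / spec.frame_rate

    assignment = _assign_tuning(spec, rng)
    norm = spec.amplitude / (spec.kernel_sd * np.sqrt(2 * np.pi))
    lam = np.zeros((spec.n_neurons, n_frames))
    for j, (kind, pref) in enumerate(assignment):
        if kind == "none":
            continue
        for i in range(n_trials):
            c, s, o = int(behavior.choice[i]), int(behavior.second_step[i]), \
                int(behavior.outcome[i])
            if kind == "choice":
                gate, center = c == pref, choice_times[i]
            elif kind == "second_step_pre":
                gate, center = s == pref, 0.5 * (choice_times[i] + outcome_times[i])
            elif kind == "second_step_post":
                gate, center = s == pref, outcome_times[i] + 0.25
            elif kind == "outcome_left":
                gate, center = (s == 1 and o == pref), outcome_times[i] + 0.25
            else:  # outcome_right
                gate, center = (s == 0 and o == pref), outcome_times[i] + 0.25
            if gate:
                a = max(int((center - 4 * spec.kernel_sd) * spec.frame_rate), 0)
                b = min(int((center + 4 * spec.kernel_sd) * spec.frame_rate) + 1, n_frames)
                lam[j, a:b] += norm * np.exp(
                    -0.5 * ((frame_t[a:b] - center) / spec.kernel_sd) ** 2)

    lam /= spec.frame_rate                       # events per frame
    bump_rate = lam.mean() * spec.frame_rate     # Hz, population mean
    baseline = max(spec.mean_rate - bump_rate, spec.min_baseline)
    lam += baseline / spec.frame_rate
    activity = rng.poisson(lam).astype(float)
    return NeuralSession(activity=activity, choice_times=choice_times,
                         outcome_times=outcome_times, behavior=behavior,
                         frame_rate=spec.frame_rate)


def generate_neural_cohort(
    behavior_sessions: Sequence[Session],
    spec: NeuralSpec,
    rng: np.random.Generator,
) -> list[NeuralSession]:
    """One synthetic neural session per behavioural session."""
    return [generate_neural_session(b, spec, rng) for b in behavior_sessions]
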