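import numpy as np
import pytest

from twostep.agents import AgentParams, simulate_agent
from twostep.synth import CohortSpec, generate_behavior_cohort
from twostep.task import TaskConfig


class ScriptedRng:
    """Stand-in RNG whose uniform draws follow a scripted sequence."""

    def __init__(self, values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)


@pytest.fixture
def scripted_rng():
    return ScriptedRng


@pytest.fixture(scope="session")
def toy_session():
    """20-trial session from the full mixture model (fixed seed)."""
    params = AgentParams(G_mf=2.0, G_mo=1.5, G_mb=3.0, B_c=0.2, B_r=0.3,
                         P_c=1.0, P_m=0.8)
    return simulate_agent(params, TaskConfig(), 20, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 2 sessions x 300 trials of full-model behaviour."""
    spec = CohortSpec(n_subjects=6, sessions_per_subject=2, trials_per_session=300)
    return generate_behavior_cohort(spec, np.random.default_rng(0))
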