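import numpy as np
import pytest

import aarl
from aarl.models import ParamVector
from aarl.synthetic import CohortConfig, default_generating_prior, generate_cohort


@pytest.fixture(scope="session")
def winning_spec():
    return aarl.ModelSpec("asym_lr_asym_sens")


@pytest.fixture(scope="session")
def schedule():
    return aarl.generate_accepted_schedule(aarl.TaskConfig(), seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """40 agents, 200 trials, default study conditions."""
    return generate_cohort(CohortConfig(n_participants=40, seed=8))


@pytest.fixture(scope="session")
def sym_session(schedule):
    """One session simulated from the symmetric two-parameter model."""
    spec = aarl.ModelSpec("sym")
    params = ParamVector.from_transformed(spec, alpha=0.4, beta=3.0)
    return aarl.simulate_agent(schedule, spec, params, seed=5)


@pytest.fixture(scope="session")
def fitted_small(small_cohort, winning_spec):
    """EM fit of the winning model on the 40-agent cohort (shared: slow)."""
    from aarl.fitting import em_fit
    return em_fit(small_cohort.sessions, winning_spec, seed=8)
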