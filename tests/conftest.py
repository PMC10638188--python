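import numpy as np
import pytest

from bioen.demand import DemandParams
from bioen.series import TrialSeries
from bioen.synthetic import (SyntheticConfig, default_params,
                             generate_subject, generate_trial)


@pytest.fixture(scope="session")
def mean_params():
    """Cohort-mean ground-truth parameter set."""
    return default_params()


@pytest.fixture(scope="session")
def mean_demand() -> DemandParams:
    return default_params().demand


@pytest.fixture(scope="session")
def synth_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def subject1(synth_config):
    return generate_subject(synth_config, seed=1)


@pytest.fixture(scope="session")
def fit_trial1(subject1, synth_config):
    """Seeded noisy fitting trial with its noise-free truth and exhaustion
    time; shared across tests to avoid regenerating."""
    trial, truth, t_ex = generate_trial(subject1, config=synth_config,
                                        seed=101)
    return trial, truth, t_ex


def constant_trial(n=201, u1=0.0, u2=0.0, y=None):
    """Uniform-grid trial with constant inputs, for equilibrium checks."""
    t = np.arange(n) * 2.0
    yy = None if y is None else np.full(n, float(y))
    return TrialSeries(t=t, u1=np.full(n, float(u1)),
                       u2=np.full(n, float(u2)), y=yy)
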