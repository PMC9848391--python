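import numpy as np
import pytest

from rrow.behavior import parse_visits
from rrow.synthetic import (
    EnsembleConfig,
    SessionConfig,
    SpikeTrain,
    simulate_ensemble,
    simulate_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_session():
    """One default simulated session shared across read-only tests."""
    return simulate_session(SessionConfig(seed=7))


@pytest.fixture(scope="session")
def default_visits(default_session):
    return parse_visits(default_session)


@pytest.fixture(scope="session")
def short_session():
    return simulate_session(SessionConfig(session_duration=600.0, seed=11))


@pytest.fixture(scope="session")
def small_ensemble(short_session):
    trains, cells = simulate_ensemble(
        short_session,
        EnsembleConfig(n_cells=6, base_rate_range=(3.0, 8.0), seed=21),
        session_duration=600.0,
    )
    return trains, cells


def poisson_train(rate, duration, seed, cell_id=0):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    return SpikeTrain(cell_id=cell_id, times=np.sort(rng.uniform(0, duration, n)), duration=duration)


@pytest.fixture
def poisson_train_factory():
    return poisson_train
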