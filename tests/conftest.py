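import numpy as np
import pytest

from aaconflict import spectral, synth, task


@pytest.fixture(scope="session")
def default_config() -> task.TaskConfig:
    return task.TaskConfig()


@pytest.fixture(scope="session")
def default_session(default_config):
    return task.generate_session(default_config, seed=11)


@pytest.fixture(scope="session")
def played_session(default_config, default_session):
    logs, summary = task.run_session(
        default_session, task.ThresholdPolicy(), default_config, seed=21
    )
    return logs, summary


@pytest.fixture(scope="session")
def coupled_fixture():
    return synth.make_fixture("coupled_lagged", seed=5, n_trials=40)


@pytest.fixture(scope="session")
def null_fixture():
    return synth.make_fixture("null", seed=7, n_trials=40)


@pytest.fixture(scope="session")
def coupled_epochs_100hz(coupled_fixture):
    ep = spectral.epoch(coupled_fixture, "turnaround", (-2500.0, 1500.0))
    return spectral.resample_epochs(ep, 100.0)


@pytest.fixture(scope="session")
def null_epochs_100hz(null_fixture):
    ep = spectral.epoch(null_fixture, "turnaround", (-2500.0, 1500.0))
    return spectral.resample_epochs(ep, 100.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
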