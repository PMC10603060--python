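import numpy as np
import pytest

from popgate.recordings import generate_recording, sample_neurons
from popgate.rnn import train_rank_one
from popgate.task import TaskParams


@pytest.fixture(scope="session")
def task_params():
    return TaskParams()


@pytest.fixture(scope="session")
def trained_net(task_params):
    """A rank-one network trained at the package's default budget.

    Expensive (about a minute); shared across the suite.
    """
    net, log = train_rank_one(task_params, N=512, n_trials=320_000, seed=0)
    return net, log


@pytest.fixture(scope="session")
def a1_recording():
    specs = sample_neurons(130, seed=0, preset="a1")
    return generate_recording(specs, 50, seed=1), specs


@pytest.fixture(scope="session")
def pfc_recording():
    specs = sample_neurons(130, seed=2, preset="pfc")
    return generate_recording(specs, 50, seed=3), specs


@pytest.fixture(scope="session")
def null_recording():
    """Generator with all effect sizes zero: no structure of any kind."""
    from popgate.recordings import EffectSizes

    eff = EffectSizes(ctx_mod_mean=0.0, ctx_mod_sd=0.0, sensory_sd_hz=0.0, gate_sd_hz=0.0)
    specs = sample_neurons(130, effects=eff, seed=4)
    return generate_recording(specs, 50, seed=5), specs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
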