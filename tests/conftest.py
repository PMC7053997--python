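import numpy as np
import pytest

from gpcrdyn import synth


@pytest.fixture(scope="session")
def toy_spec():
    return synth.build_toy_receptor()


@pytest.fixture(scope="session")
def small_dataset(toy_spec):
    """A short simulated switching trajectory at study-default noise/rates."""
    cfg = synth.SimConfig(n_frames=4000, seed=11)
    return synth.simulate_switching_trajectory(toy_spec, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
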