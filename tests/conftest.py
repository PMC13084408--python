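import numpy as np
import pytest

from burstlink import SimConfig, build_kernel, generate_session


@pytest.fixture(scope="session")
def kernel():
    return build_kernel()


@pytest.fixture(scope="session")
def sc_session():
    """Small SC-like session with delayed-task block, shared across tests."""
    cfg = SimConfig(n_neurons=4, n_trials_per_condition=30,
                    contrasts=(20, 100), polarities=("dark",), seed=11)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def v1_session():
    cfg = SimConfig.v1_like(n_neurons=4, n_trials_per_condition=30,
                            contrasts=(20, 100), polarities=("dark",), seed=12)
    return generate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
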