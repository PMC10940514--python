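import numpy as np
import pytest

from mesn import (
    ESNConfig,
    SyntheticSpec,
    TopologyConfig,
    generate_reservoir,
    generate_separable_features,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_mats():
    """A 60-unit modular reservoir with 3 inputs, shared across tests."""
    cfg = TopologyConfig(n=60, modules=3, p_intra=0.3, p_inter=0.1, seed=7)
    return generate_reservoir(cfg, rho_target=0.85, n_inputs=3)


@pytest.fixture(scope="session")
def big_mats():
    """The experiment-scale reservoir (N=600, M=6, P1=0.05, P2=0.02)."""
    cfg = TopologyConfig(n=600, modules=6, p_intra=0.05, p_inter=0.02, seed=11)
    return generate_reservoir(cfg, rho_target=0.85, n_inputs=128)


@pytest.fixture(scope="session")
def separable_dataset():
    """Well-separated band-power-like features for readout tests."""
    return generate_separable_features(150, dim=128, gap=0.5, noise_sd=0.05, seed=3)


@pytest.fixture
def esn_config():
    return ESNConfig(alpha=0.25, ridge_lambda=1e-6)


@pytest.fixture(scope="session")
def tiny_trials():
    """A small synthetic session reused by feature and pipeline tests."""
    from mesn import generate_trials

    spec = SyntheticSpec(n_trials=12, seed=5)
    return generate_trials(spec)
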