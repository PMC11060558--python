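import numpy as np
import pytest

from cebsim import NetworkConfig, build_default_network
from cebsim.protocol import LesionConfig, ProtocolConfig, make_engine
from cebsim.plasticity import PlasticityRuleParams


@pytest.fixture(scope="session")
def small_network():
    """Wired scaffold at 5% scale (shared, read-only)."""
    return build_default_network(NetworkConfig(scale_factor=0.05, seed=3))


@pytest.fixture(scope="session")
def small_protocol():
    return ProtocolConfig(n_blocks=1, trials_per_block=3, n_seeds=1)


@pytest.fixture()
def small_engine(small_network):
    return make_engine(small_network, LesionConfig("control"),
                       PlasticityRuleParams(), np.random.default_rng(0),
                       plasticity_enabled=False)
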