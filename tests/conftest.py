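import numpy as np
import pytest

import kurastab as ks


@pytest.fixture(scope="session")
def net34():
    """34-node modular synthetic network (dat-like scale)."""
    return ks.generate_network(
        ks.SyntheticNetworkSpec(n_nodes=34, n_modules=4, p_within=0.6,
                                p_between=0.1, seed=11)
    )


@pytest.fixture(scope="session")
def net8():
    """8-node strongly modular fixture used for fast dynamics tests."""
    return ks.generate_network(
        ks.SyntheticNetworkSpec(n_nodes=8, n_modules=2, p_within=0.9,
                                p_between=0.15, seed=0)
    )


@pytest.fixture(scope="session")
def traj8(net8):
    """One stabilised 2,000-step trajectory on the 8-node fixture."""
    freqs = ks.sample_frequencies(net8.n_nodes, seed=5)
    system = ks.build_system(net8, freqs, k_global=150.0)
    return ks.simulate(system, n_steps=2000, init_phases=3, burn_in=100)


def two_node_network(weight=0.3, length_mm=40.0):
    w = np.array([[0.0, weight], [weight, 0.0]])
    ln = np.array([[0.0, length_mm], [length_mm, 0.0]])
    return ks.StructuralNetwork(w, ln)


@pytest.fixture
def net2():
    return two_node_network()
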