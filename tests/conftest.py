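import numpy as np
import pytest

import boolsteady as bs

# Exact stationary probabilities of the 3-node example under unit rates and a
# uniform initial condition, derived by first-step analysis on its 10 arcs.
TOY_EXACT = {"011": 17 / 48, "100": 18 / 48, "101": 13 / 48}
TOY_NODE_EXACT = {"A": 31 / 48, "B": 17 / 48, "C": 30 / 48}


@pytest.fixture(scope="session")
def toy3():
    return bs.fixtures.toy3()


@pytest.fixture(scope="session")
def oscillator():
    return bs.fixtures.oscillator()


@pytest.fixture(scope="session")
def input_split():
    return bs.fixtures.input_split()


@pytest.fixture
def unit_rates(toy3):
    return bs.TransitionRates.uniform(toy3)


@pytest.fixture
def toy_table(toy3):
    return bs.enumerate_transitions(toy3)


@pytest.fixture
def toy_K(toy3, toy_table, unit_rates):
    return bs.build_kinetic_matrix(toy_table, unit_rates, toy3)


@pytest.fixture
def uniform_x0(toy3):
    return np.full(toy3.n_states, 1 / toy3.n_states)


def toy_exact_vector(net):
    """TOY_EXACT as a full 8-state probability vector."""
    x = np.zeros(net.n_states)
    for label, p in TOY_EXACT.items():
        x[net.state_index([int(b) for b in label]) - 1] = p
    return x
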