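import numpy as np
import pytest

from predsensor import EpsilonMachine, random_epsilon_machine


@pytest.fixture
def period2_machine():
    """Deterministic alternator: state A emits 0 -> B, state B emits 1 -> A.

    The output is the period-2 sequence ...0101..., so every statistic has a
    closed form: C_mu = rho_mu = I[X_t;X_{t+1}] = ln 2.
    """
    T = np.zeros((2, 2, 2))
    T[0, 1, 0] = 1.0  # A emits 0, goes to B
    T[1, 0, 1] = 1.0  # B emits 1, goes to A
    return EpsilonMachine(2, 2, T)


@pytest.fixture
def iid_machine():
    """Single-state machine: an IID biased coin (p(0) = 0.3)."""
    T = np.zeros((2, 1, 1))
    T[0, 0, 0] = 0.3
    T[1, 0, 0] = 0.7
    return EpsilonMachine(1, 2, T)


@pytest.fixture
def small_machine():
    return random_epsilon_machine(5, seed=42)


@pytest.fixture
def medium_machine():
    return random_epsilon_machine(30, seed=3)
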