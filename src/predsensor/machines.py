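"""Random unifilar hidden Markov models (epsilon-machines) as environments.

An environment is the output process of a unifilar HMM: hidden causal states
``sigma`` emit symbols ``x`` and move to a successor state that is uniquely
determined by ``(sigma, x)``.  The labeled transition tensor has entries

    T[x, sigma', sigma] = Pr(S_{t+1} = sigma', X_t = x | S_t = sigma)

so each source column sums to 1 over ``(x, sigma')`` jointly.  Random
environments are drawn by giving every state an emission probability for
symbol 0 uniform on (0, 1) and independent uniformly random successor states
for each symbol (self-loops and shared successors allowed).

All information quantities are in nats (natural log).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._linalg import stationary_dense

__all__ = [
    "EpsilonMachine",
    "EnvironmentStats",
    "random_epsilon_machine",
    "stationary_distribution",
    "statistical_complexity",
    "total_correlation_rate",
    "symbol_pair_information",
    "environment_stats",
]

_ATOL = 1e-12


@dataclass
class EpsilonMachine:
    """A unifilar edge-emitting hidden Markov model.

    Attributes
    ----------
    num_states
        Number of causal states ``|S|``.
    alphabet_size
        Number of output symbols (2 throughout the study).
    transition
        Array of shape ``(alphabet_size, num_states, num_states)`` with
        ``transition[x, dest, src]`` the joint probability of emitting ``x``
        and moving ``src -> dest``.
    state_labels
        Optional identifiers for the states.
    seed
        Seed used to generate the machine, if any (provenance only).
    """

    num_states: int
    alphabet_size: int
    transition: np.ndarray
    state_labels: Sequence | None = None
    seed: int | None = None

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        self.validate()

    def validate(self) -> None:
        T = self.transition
        if T.shape != (self.alphabet_size, self.num_states, self.num_states):
            raise ValueError(f"transition tensor has shape {T.shape}, "
                             f"expected {(self.alphabet_size, self.num_states, self.num_states)}")
        if np.any(T < -_ATOL) or np.any(T > 1 + _ATOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        col = T.sum(axis=(0, 1))
        if np.any(np.abs(col - 1.0) > _ATOL):
            raise ValueError("per-state outgoing probabilities must sum to 1")
        # unifilarity: for each (src, x) at most one positive destination
        if np.any((T > 0).sum(axis=1) > 1):
            raise ValueError("machine is not unifilar: some (state, symbol) has "
                             "more than one possible successor")

    @property
    def emission(self) -> np.ndarray:
        """``emission[x, sigma] = Pr(X_t = x | S_t = sigma)``."""
        return self.transition.sum(axis=1)

    @property
    def successor(self) -> np.ndarray:
        """``successor[x, sigma]``: the unifilar successor of ``sigma`` on ``x``.

        Where ``Pr(x | sigma) = 0`` the stored index is arbitrary (never used
        with positive probability).
        """
        return self.transition.argmax(axis=1)

    @property
    def symbol_marginal_chain(self) -> np.ndarray:
        """Column-stochastic state chain ``sum_x T^(x)``."""
        return self.transition.sum(axis=0)


@dataclass
class EnvironmentStats:
    """Exact process statistics of an environment.

    ``markov_ratio`` is ``I[X_t; X_{t+1}] / rho_mu`` — how much of the
    one-step predictive ceiling a memory of just the last symbol captures —
    and is NaN when ``rho_mu = 0``.
    """

    stationary: np.ndarray
    statistical_complexity: float
    total_correlation_rate: float
    symbol_pair_information: float
    markov_ratio: float = field(init=False)

    def __post_init__(self):
        rho = self.total_correlation_rate
        self.markov_ratio = self.symbol_pair_information / rho if rho > 0 else float("nan")


def random_epsilon_machine(num_states: int, seed: int | None = None) -> EpsilonMachine:
    """Draw a random binary-alphabet unifilar HMM.

    For each state, the probability of emitting 0 is uniform on (0, 1) and
    the successor state after each symbol is uniform over all states
    (independently per symbol; self-loops allowed).  The construction is
    unifilar by design.  Identical seeds reproduce the machine bit-exactly.
    """
    if num_states < 1:
        raise ValueError("num_states must be >= 1")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(size=num_states)
    succ = rng.integers(num_states, size=(2, num_states))
    T = np.zeros((2, num_states, num_states))
    src = np.arange(num_states)
    T[0, succ[0], src] = p0
    T[1, succ[1], src] = 1.0 - p0
    return EpsilonMachine(num_states, 2, T, seed=seed)


def stationary_distribution(machine: EpsilonMachine) -> np.ndarray:
    """Stationary distribution over causal states.

    The leading eigenvector of the symbol-marginal chain ``sum_x T^(x)``.
    When the state graph is reducible the Cesaro (time-averaged) limit from
    the uniform start is returned, which gives transient states zero mass
    with a deterministic tie-break between recurrent classes.
    """
    return stationary_dense(machine.symbol_marginal_chain)


def statistical_complexity(machine: EpsilonMachine) -> float:
    """Statistical complexity ``C_mu = H[S]`` in nats (memory needed to predict)."""
    from .metrics import entropy

    return entropy(stationary_distribution(machine))


def total_correlation_rate(machine: EpsilonMachine) -> float:
    """Total correlation rate ``rho_mu = I[past; X_{t+1}]`` in nats.

    Computed as ``I[S_t; X_t]`` at stationarity: the causal state is a
    sufficient statistic of the past, so the information the infinite past
    carries about the next symbol equals the information the current state
    carries about the symbol it is about to emit.
    """
    from .metrics import mutual_information

    p = stationary_distribution(machine)
    joint = (machine.emission * p).T  # (sigma, x)
    return mutual_information(joint)


def symbol_pair_information(machine: EpsilonMachine) -> float:
    """Single-symbol-pair mutual information ``I[X_t; X_{t+1}]`` in nats.

    What a sensor that stores only the current symbol (a Markov model of the
    input) would capture; the ratio to ``rho_mu`` measures how Markovian the
    environment is.
    """
    from .metrics import mutual_information

    p = stationary_distribution(machine)
    e = machine.emission  # (x, sigma)
    succ = machine.successor
    A = machine.alphabet_size
    joint = np.zeros((A, A))
    for x in range(A):
        # mass p(sigma) e(x|sigma) lands in state succ[x, sigma], then emits x'
        w = p * e[x]
        joint[x] = e[:, succ[x]] @ w
    return mutual_information(joint)


def environment_stats(machine: EpsilonMachine) -> EnvironmentStats:
    """All exact process statistics of an environment in one pass."""
    from .metrics import entropy, mutual_information

    p = stationary_distribution(machine)
    stats = EnvironmentStats(
        stationary=p,
        statistical_complexity=entropy(p),
        total_correlation_rate=mutual_information((machine.emission * p).T),
        symbol_pair_information=symbol_pair_information(machine),
    )
    return stats
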