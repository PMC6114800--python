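"""Random and optimal conditionally Markovian sensors.

A sensor with ``N`` states updates its state distribution on each input
symbol ``x`` through a column-stochastic matrix ``M^(x)``:

    p(r_{t+1}) = M^(x_t) p(r_t),   M[x, dest, src] = Pr(R_{t+1}=dest | X_t=x, R_t=src).

Four families are provided:

* dense Dirichlet — every column an iid ``Dirichlet(alpha * 1_N)`` draw; the
  concentration ``alpha`` dials stochasticity (large ``alpha`` -> columns near
  uniform, i.e. highly nondeterministic wiring);
* heterogeneous Dirichlet — a fresh ``alpha(x, r) ~ U(0, alpha_high)`` per
  column, modelling input- and state-dependent stochasticity;
* sparse ``k``-support — each column supported on ``k`` random destination
  states with a ``Dirichlet(alpha * 1_k)`` distribution on the support; small
  ``k`` means near-deterministic wiring, ``k = 1`` fully deterministic;
* the optimal sensor — a copy of the environment's own causal-state dynamics,
  which saturates both metric bounds (``I_pred = rho_mu``, ``I_mem = C_mu``).

Dirichlet draws use normalized iid Gamma(alpha, 1) variates, resampling the
(floating-point-only) degenerate all-zero event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .machines import EpsilonMachine

__all__ = [
    "Sensor",
    "dirichlet_sensor",
    "heterogeneous_dirichlet_sensor",
    "sparse_sensor",
    "optimal_sensor",
    "row_sum_statistics",
]

_ATOL = 1e-12


@dataclass
class Sensor:
    """A conditionally Markovian sensor.

    ``support_size`` is ``k`` for sparse sensors (every column has at most
    ``k`` positive entries) or ``"dense"``.  ``provenance`` records the
    generating family and its parameters.
    """

    num_states: int
    alphabet_size: int
    transition: np.ndarray
    support_size: int | str = "dense"
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        self.validate()

    def validate(self) -> None:
        M = self.transition
        if M.shape != (self.alphabet_size, self.num_states, self.num_states):
            raise ValueError(f"transition tensor has shape {M.shape}, expected "
                             f"{(self.alphabet_size, self.num_states, self.num_states)}")
        if np.any(M < -_ATOL) or np.any(M > 1 + _ATOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        cols = M.sum(axis=1)
        if np.any(np.abs(cols - 1.0) > _ATOL):
            raise ValueError("every (symbol, source) column must sum to 1")
        if isinstance(self.support_size, int):
            if np.any((M > 0).sum(axis=1) > self.support_size):
                raise ValueError("a column exceeds the declared support size")


def _check_args(N: int, alpha: float) -> None:
    if N < 1:
        raise ValueError("N must be >= 1")
    if not alpha > 0:
        raise ValueError("alpha must be > 0")


def _dirichlet_columns(rng: np.random.Generator, alpha: np.ndarray,
                       shape: tuple[int, ...]) -> np.ndarray:
    """Columns of iid Gamma(alpha) normalized along axis 1 (destinations)."""
    g = rng.gamma(alpha, 1.0, size=shape)
    total = g.sum(axis=1, keepdims=True)
    while np.any(total == 0):  # degenerate underflow; essentially unreachable
        bad = np.broadcast_to(total == 0, shape)
        g[bad] = rng.gamma(np.broadcast_to(alpha, shape)[bad], 1.0)
        total = g.sum(axis=1, keepdims=True)
    return g / total


def dirichlet_sensor(N: int, alpha: float, alphabet_size: int = 2,
                     seed: int | None = None) -> Sensor:
    """Fully nondeterministic random sensor: iid Dirichlet(alpha 1_N) columns."""
    _check_args(N, alpha)
    rng = np.random.default_rng(seed)
    M = _dirichlet_columns(rng, np.full((alphabet_size, N, N), float(alpha)),
                           (alphabet_size, N, N))
    return Sensor(N, alphabet_size, M, "dense",
                  {"family": "dirichlet", "alpha": alpha, "seed": seed})


def heterogeneous_dirichlet_sensor(N: int, alpha_high: float = 10.0,
                                   alphabet_size: int = 2,
                                   seed: int | None = None) -> Sensor:
    """Random sensor with per-(symbol, source) concentration alpha ~ U(0, alpha_high)."""
    _check_args(N, alpha_high)
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(0.0, alpha_high, size=(alphabet_size, 1, N))
    M = _dirichlet_columns(rng, np.broadcast_to(alpha, (alphabet_size, N, N)),
                           (alphabet_size, N, N))
    return Sensor(N, alphabet_size, M, "dense",
                  {"family": "heterogeneous", "alpha_high": alpha_high, "seed": seed})


def sparse_sensor(N: int, k: int, alpha: float, alphabet_size: int = 2,
                  seed: int | None = None) -> Sensor:
    """Near-deterministic sensor: k-destination support per column.

    Each (symbol, source) column places a Dirichlet(alpha 1_k) draw on ``k``
    distinct destination states chosen uniformly without replacement.
    """
    _check_args(N, alpha)
    if not 1 <= k <= N:
        raise ValueError("k must satisfy 1 <= k <= N")
    rng = np.random.default_rng(seed)
    M = np.zeros((alphabet_size, N, N))
    for x in range(alphabet_size):
        for r in range(N):
            support = rng.choice(N, size=k, replace=False)
            M[x, support, r] = _dirichlet_columns(
                rng, np.full((1, k), float(alpha)), (1, k))[0]
    return Sensor(N, alphabet_size, M, k,
                  {"family": "sparse", "k": k, "alpha": alpha, "seed": seed})


def optimal_sensor(machine: EpsilonMachine) -> Sensor:
    """The minimal optimal predictive sensor: the environment's own machine.

    Sensor states mirror causal states and transitions copy the unifilar
    successor map, so the sensor is deterministic.  Where a symbol cannot be
    emitted from a state the transition is a self-loop (any choice is valid
    there; a self-loop keeps the construction deterministic and reproducible).
    """
    S = machine.num_states
    A = machine.alphabet_size
    e = machine.emission
    succ = machine.successor
    M = np.zeros((A, S, S))
    src = np.arange(S)
    for x in range(A):
        dest = np.where(e[x] > 0, succ[x], src)
        M[x, dest, src] = 1.0
    return Sensor(S, A, M, 1, {"family": "optimal"})


def row_sum_statistics(sensor: Sensor) -> pd.DataFrame:
    """Per-symbol dispersion of row sums ``sum_src M[x, dest, src]``.

    The row sum is the total incoming weight of a destination state.  Its mean
    over rows is exactly 1 (each of the N columns contributes total mass 1);
    its concentration around 1 (a ratio of Gamma(N alpha) variates for dense
    Dirichlet sensors) is what drives large nondeterministic sensors toward
    nonspecificity.
    """
    rows = sensor.transition.sum(axis=2)  # (x, dest)
    return pd.DataFrame({
        "symbol": np.arange(sensor.alphabet_size),
        "mean": rows.mean(axis=1),
        "var": rows.var(axis=1),
        "min": rows.min(axis=1),
        "max": rows.max(axis=1),
    })
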