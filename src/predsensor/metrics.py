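"""Exact sensor metrics via the joint environment-sensor chain.

The pair ``(sigma_t, r_t)`` of causal state and sensor state is itself a
Markov chain with column-stochastic transition

    J[(sigma', r'), (sigma, r)] = sum_x M^(x)[r', r] * T^(x)[sigma', sigma].

Its stationary distribution ``p_ss(sigma, r)`` (the normalized eigenvector of
eigenvalue 1) yields every metric exactly:

* memory ``I_mem = I[R; S]`` — how much the sensor knows about the
  environment's predictive state;
* predictive information ``I_pred = I[R; X_next]`` — how much it knows about
  the next symbol;
* the nonspecificity bound ``I'_mem = D_KL[p_ss(r, sigma) || p_ss(sigma)/N]``,
  an upper bound on ``I_mem`` that measures deviation from the uniform
  nonspecific sensor.

The data-processing chain R -> S -> X_next gives the exact bound chain
``0 <= I_pred <= I_mem <= min(C_mu, I'_mem)`` and ``I_pred <= rho_mu``.

The steady state is never computed from the dense ``|S|N x |S|N`` matrix:
one step of the joint chain factorizes as ``sum_x T^(x) P M^(x)^T`` on the
``(|S|, N)``-shaped distribution ``P``, and the unifilar ``T^(x)`` apply as
a weighted scatter, so each iteration costs ``O(|S| N^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from ._linalg import ConvergenceError, stationary_exact, stationary_from_matvec
from .machines import EpsilonMachine, EnvironmentStats, environment_stats, stationary_distribution
from .sensors import Sensor

__all__ = [
    "entropy",
    "mutual_information",
    "JointChain",
    "StationaryJoint",
    "SensorMetrics",
    "joint_transition",
    "steady_state_joint",
    "memory_information",
    "memory_kl_bound",
    "predictive_distribution",
    "predictive_information",
    "sensor_metrics",
]


def _validate_dist(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {p.sum()!r})")
    return p


def entropy(dist: np.ndarray) -> float:
    """Shannon entropy in nats, with the convention 0 ln 0 = 0."""
    p = _validate_dist(dist, "dist")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def mutual_information(joint: np.ndarray) -> float:
    """Mutual information in nats of a joint probability array.

    The two variables are the first axis and the remaining axes flattened.
    Nonnegative; zero iff the joint factorizes.
    """
    q = _validate_dist(joint, "joint")
    q = q.reshape(q.shape[0], -1)
    a = q.sum(axis=1)
    b = q.sum(axis=0)
    mask = q > 0
    # q > 0 forces both marginals > 0; sum the logs to dodge underflow in a*b
    la = np.log(a, out=np.zeros_like(a), where=a > 0)
    lb = np.log(b, out=np.zeros_like(b), where=b > 0)
    ref = (la[:, None] + lb[None, :])[mask]
    val = float(np.sum(q[mask] * (np.log(q[mask]) - ref)))
    return max(val, 0.0)


@dataclass
class JointChain:
    """The coupled Markov chain on (causal state, sensor state) pairs.

    Flat index layout is environment-major: ``i = sigma * N + r``.
    """

    machine: EpsilonMachine
    sensor: Sensor

    def __post_init__(self):
        if self.machine.alphabet_size != self.sensor.alphabet_size:
            raise ValueError("machine and sensor alphabet sizes differ")

    @property
    def dim(self) -> int:
        return self.machine.num_states * self.sensor.num_states

    def flat_index(self, sigma: int, r: int) -> int:
        return sigma * self.sensor.num_states + r

    def pair_of(self, i: int) -> tuple[int, int]:
        return divmod(i, self.sensor.num_states)

    def step(self, P: np.ndarray) -> np.ndarray:
        """One joint-chain step on a distribution shaped ``(|S|, N)``."""
        e = self.machine.emission
        succ = self.machine.successor
        M = self.sensor.transition
        out = np.zeros_like(P)
        for x in range(self.machine.alphabet_size):
            moved = (e[x][:, None] * P) @ M[x].T
            np.add.at(out, succ[x], moved)
        return out

    @cached_property
    def matrix(self) -> np.ndarray:
        """Dense column-stochastic matrix; entry [(sigma',r'),(sigma,r)]."""
        T = self.machine.transition
        M = self.sensor.transition
        S, N = self.machine.num_states, self.sensor.num_states
        J = np.zeros((S * N, S * N))
        for x in range(self.machine.alphabet_size):
            J += np.kron(T[x], M[x])
        return J


@dataclass
class StationaryJoint:
    """Steady-state distribution ``p_ss(sigma, r)`` with cached marginals."""

    p: np.ndarray  # shape (|S|, N)

    @cached_property
    def p_sigma(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @cached_property
    def p_r(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def num_sensor_states(self) -> int:
        return self.p.shape[1]


def joint_transition(machine: EpsilonMachine, sensor: Sensor) -> JointChain:
    """Build the coupled (sigma, r) chain; raises on alphabet mismatch."""
    return JointChain(machine, sensor)


def steady_state_joint(
    chain: JointChain,
    init: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> StationaryJoint:
    """Stationary distribution of the joint chain.

    Default init is ``p_ss(sigma) (x) uniform(N)`` — the environment already
    at stationarity, the sensor uninformed.  For reducible or periodic joint
    chains (common with deterministic sensors) the result is the Cesaro
    time-average from that init, which is deterministic and reproducible.

    Power iteration on the structured one-step map is the fast path; if the
    chain mixes too slowly for it the exact recurrent-class solver takes
    over on the dense matrix (up to dimension 4096, beyond which the
    convergence failure is re-raised with its residual).
    """
    S = chain.machine.num_states
    N = chain.sensor.num_states
    if init is None:
        init = np.outer(stationary_distribution(chain.machine), np.full(N, 1.0 / N))
    else:
        init = _validate_dist(init, "init").reshape(S, N)
    try:
        flat = stationary_from_matvec(
            lambda v: chain.step(v.reshape(S, N)).ravel(),
            init.ravel(),
            tol=tol,
            max_iter=max_iter,
        )
    except ConvergenceError:
        if chain.dim > 4096:
            raise
        flat = stationary_exact(chain.matrix, init.ravel())
    return StationaryJoint(flat.reshape(S, N))


def memory_information(sj: StationaryJoint) -> float:
    """Memory ``I_mem = I[R; S]`` in nats from the stationary joint."""
    return mutual_information(sj.p)


def memory_kl_bound(sj: StationaryJoint, N: int | None = None) -> float:
    """Nonspecificity bound ``I'_mem = D_KL[p_ss(r, sigma) || p_ss(sigma)/N]``.

    Zero exactly when the sensor is nonspecific (``p(r|sigma) = 1/N``) —
    whatever the sensor-state marginal; always ``>= I_mem``.
    """
    if N is None:
        N = sj.num_sensor_states
    p = sj.p
    ref = np.broadcast_to(sj.p_sigma[:, None] / N, p.shape)
    mask = p > 0
    if np.any(mask & (ref <= 0)):
        raise ValueError("joint has mass on states with zero stationary probability")
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(ref[mask]))))


def predictive_distribution(sj: StationaryJoint, machine: EpsilonMachine) -> np.ndarray:
    """Joint ``p(r, x)`` of sensor state and the next symbol.

    ``p(r, x) = sum_sigma p_ss(sigma, r) Pr(x | sigma)`` where ``Pr(x|sigma)``
    is the one-step emission distribution of the current causal state — the
    first symbol the sensor has not yet consumed.
    """
    if sj.p.shape[0] != machine.num_states:
        raise ValueError("stationary joint and machine dimensions differ")
    return sj.p.T @ machine.emission.T  # (r, x)


def predictive_information(machine: EpsilonMachine, sensor: Sensor) -> float:
    """Predictive information ``I_pred = I[R; X_next]`` in nats, exactly."""
    sj = steady_state_joint(joint_transition(machine, sensor))
    return mutual_information(predictive_distribution(sj, machine))


@dataclass
class SensorMetrics:
    """All exact metrics of a (machine, sensor) pair.

    ``predictive_ratio = I_pred / rho_mu`` and ``memory_ratio = I_mem / C_mu``
    are NaN when the denominator is zero.
    """

    memory: float
    predictive: float
    memory_kl_bound: float
    env: EnvironmentStats
    predictive_ratio: float
    memory_ratio: float


def sensor_metrics(machine: EpsilonMachine, sensor: Sensor,
                   env: EnvironmentStats | None = None) -> SensorMetrics:
    """Compute I_mem, I_pred and I'_mem for one pair in one steady-state solve."""
    if env is None:
        env = environment_stats(machine)
    sj = steady_state_joint(joint_transition(machine, sensor))
    imem = memory_information(sj)
    ipred = mutual_information(predictive_distribution(sj, machine))
    rho = env.total_correlation_rate
    cmu = env.statistical_complexity
    return SensorMetrics(
        memory=imem,
        predictive=ipred,
        memory_kl_bound=memory_kl_bound(sj),
        env=env,
        predictive_ratio=ipred / rho if rho > 0 else float("nan"),
        memory_ratio=imem / cmu if cmu > 0 else float("nan"),
    )
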