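"""Direct maximization of predictive information over sensor wirings.

The sensor's columns are parameterized by unconstrained scores through the
exponential-normalization (softmax) map, so the search space is all strictly
positive column-stochastic transition tensors.  The objective is the exact
predictive information ``I_pred(machine, sensor)`` from the joint-chain
stationary eigenvector, maximized with L-BFGS-B over multiple random
restarts.

The gradient is exact, via the adjoint of the stationary-state equation:
with ``J`` the joint chain, ``p`` its stationary distribution and
``g = dI_pred/dp``, the sensitivity is obtained from one linear solve
``(I - J + p 1^T)^T lambda = g``; then ``dI/dM^(x) = Lambda^T T^(x) P`` with
``Lambda, P`` the (|S|, N)-shaped adjoint and stationary arrays, followed by
the softmax Jacobian.  This costs one dense solve per evaluation instead of
hundreds of finite-difference objective calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .machines import EpsilonMachine, stationary_distribution
from .metrics import joint_transition, predictive_distribution, steady_state_joint, StationaryJoint
from .sensors import Sensor

__all__ = ["OptimizationResult", "optimize_sensor"]


@dataclass
class OptimizationResult:
    """Outcome of a multi-restart sensor optimization.

    ``objective_trace`` is the best-so-far I_pred at each accepted iterate of
    the best restart (non-decreasing by construction).
    """

    sensor: Sensor
    objective_trace: list[float]
    restart_count: int
    best_restart_index: int
    converged: bool


def _softmax_columns(scores: np.ndarray) -> np.ndarray:
    """Map scores (A, N, N) to column-stochastic M along the destination axis."""
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _ipred_and_grad(scores: np.ndarray, machine: EpsilonMachine,
                    env_stationary: np.ndarray) -> tuple[float, np.ndarray]:
    """Exact I_pred and its gradient w.r.t. the softmax scores."""
    A_sym, N, _ = scores.shape
    S = machine.num_states
    M = _softmax_columns(scores)
    sensor = Sensor(N, A_sym, M, "dense", {"family": "softmax"})
    chain = joint_transition(machine, sensor)
    init = np.outer(env_stationary, np.full(N, 1.0 / N))
    sj = steady_state_joint(chain, init=init.ravel())
    P = sj.p  # (S, N)

    e = machine.emission  # (x, sigma)
    Q = predictive_distribution(sj, machine)  # (r, x)
    a = Q.sum(axis=1)  # p(r)
    b = Q.sum(axis=0)  # p(x)
    # dI/dQ; entries with Q = 0 contribute nothing
    logterm = np.zeros_like(Q)
    mask = Q > 0
    logterm[mask] = np.log(Q[mask]) - np.log(np.outer(a, b)[mask]) - 1.0
    ipred = float(np.sum(Q[mask] * (logterm[mask] + 1.0)))

    # g(sigma, r) = sum_x e(x|sigma) * dI/dQ(r, x)
    g = (logterm @ e).T  # (S, N)

    # adjoint solve: (I - J + p 1^T)^T lambda = g
    J = chain.matrix
    D = S * N
    p_flat = P.ravel()
    Amat = np.eye(D) - J + np.outer(p_flat, np.ones(D))
    try:
        lam = np.linalg.solve(Amat.T, g.ravel())
    except np.linalg.LinAlgError:
        lam = np.linalg.lstsq(Amat.T, g.ravel(), rcond=None)[0]
    Lam = lam.reshape(S, N)

    # dI/dM^(x)[dest, src] = sum_{sigma', sigma} Lam[sigma', dest] T^(x)[sigma', sigma] P[sigma, src]
    succ = machine.successor
    dM = np.empty_like(M)
    for x in range(A_sym):
        # T^(x)^T Lam picked out by the unifilar successor: (T^(x)^T Lam)[sigma, :] = e(x|sigma) Lam[succ_x(sigma), :]
        TtL = e[x][:, None] * Lam[succ[x]]
        dM[x] = TtL.T @ P
    # softmax Jacobian, column-wise
    inner = (dM * M).sum(axis=1, keepdims=True)
    dscores = M * (dM - inner)
    return ipred, dscores


def optimize_sensor(machine: EpsilonMachine, N: int, restarts: int = 5,
                    max_iter: int = 100, seed: int | None = None,
                    tol: float = 1e-8) -> OptimizationResult:
    """Maximize I_pred over N-state sensors with L-BFGS-B and random restarts.

    Scores are initialized iid standard normal per restart.  Returns the best
    sensor across restarts together with its monotone objective trace.  The
    final I_pred never exceeds the environment's total correlation rate (the
    data-processing ceiling); that bound is a property of the exact
    objective, not an explicit constraint.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    env_stat = stationary_distribution(machine)
    A_sym = machine.alphabet_size
    shape = (A_sym, N, N)

    best_val = -np.inf
    best_scores = None
    best_trace: list[float] = []
    best_idx = 0
    converged = False
    for idx in range(restarts):
        s0 = rng.standard_normal(shape)
        trace: list[float] = []

        def fun(flat):
            val, grad = _ipred_and_grad(flat.reshape(shape), machine, env_stat)
            return -val, -grad.ravel()

        def cb(flat):
            val = _ipred_and_grad(flat.reshape(shape), machine, env_stat)[0]
            trace.append(max(val, trace[-1]) if trace else val)

        v0 = _ipred_and_grad(s0, machine, env_stat)[0]
        trace.append(v0)
        res = minimize(fun, s0.ravel(), jac=True, method="L-BFGS-B",
                       callback=cb, options={"maxiter": max_iter, "ftol": tol})
        final = max(-res.fun, trace[-1])
        trace.append(final)
        if final > best_val:
            best_val = final
            best_scores = res.x.reshape(shape)
            best_trace = trace
            best_idx = idx
            converged = bool(res.success)

    M = _softmax_columns(best_scores)
    sensor = Sensor(N, A_sym, M, "dense",
                    {"family": "optimized", "restarts": restarts,
                     "max_iter": max_iter, "seed": seed})
    return OptimizationResult(sensor, best_trace, restarts, best_idx, converged)
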