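"""Monte Carlo simulation of coupled environment-sensor trajectories.

This is the package's independent check on the exact eigenvector method: run
the environment and the sensor forward symbol by symbol, count joint
occurrences of ``(sigma_t, r_t, x_t)`` and form plug-in mutual-information
estimates.  Alignment convention: ``x_t`` is the symbol emitted from
``sigma_t`` at time ``t``, after the sensor has reached ``r_t`` from the
earlier symbols — so ``I[r_t; sigma_t]`` estimates memory and
``I[r_t; x_t]`` estimates predictive information, matching the exact method.

Plug-in (maximum-likelihood) estimation is used throughout; the oracle is
confined to small state spaces and long trajectories where its bias is
negligible against the reported standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .machines import EpsilonMachine, stationary_distribution
from .sensors import Sensor

__all__ = ["Trajectory", "simulate", "plugin_estimates", "PluginEstimates"]


@dataclass
class Trajectory:
    """A sampled path of causal states, sensor states and symbols."""

    states: np.ndarray
    sensor_states: np.ndarray
    symbols: np.ndarray
    length: int
    seed: int | None


def simulate(machine: EpsilonMachine, sensor: Sensor, length: int,
             seed: int | None = None, init_state: int | None = None,
             init_sensor: int | None = None) -> Trajectory:
    """Simulate ``length`` coupled steps.

    The initial causal state is drawn from the exact stationary distribution
    (unless ``init_state`` is given) so only the sensor marginal needs
    burn-in; the initial sensor state is uniform unless ``init_sensor`` is
    given.  Fully reproducible from ``seed``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if machine.alphabet_size != sensor.alphabet_size:
        raise ValueError("machine and sensor alphabet sizes differ")
    S, N = machine.num_states, sensor.num_states
    if init_state is not None and not 0 <= init_state < S:
        raise ValueError("init_state out of range")
    if init_sensor is not None and not 0 <= init_sensor < N:
        raise ValueError("init_sensor out of range")
    rng = np.random.default_rng(seed)

    ecum = machine.emission.cumsum(axis=0)  # (x, sigma) cumulative over symbols
    succ = machine.successor
    mcum = sensor.transition.cumsum(axis=1)  # (x, dest, src) cumulative over dest

    if init_state is None:
        p0 = stationary_distribution(machine)
        sigma = int(rng.choice(S, p=p0))
    else:
        sigma = init_state
    r = int(rng.integers(N)) if init_sensor is None else init_sensor

    states = np.empty(length, dtype=np.int64)
    sensors = np.empty(length, dtype=np.int64)
    symbols = np.empty(length, dtype=np.int64)
    u_sym = rng.uniform(size=length)
    u_sen = rng.uniform(size=length)
    for t in range(length):
        states[t] = sigma
        sensors[t] = r
        x = int(np.searchsorted(ecum[:, sigma], u_sym[t]))
        x = min(x, machine.alphabet_size - 1)
        symbols[t] = x
        sigma = int(succ[x, sigma])
        rn = int(np.searchsorted(mcum[x, :, r], u_sen[t]))
        r = min(rn, N - 1)
    return Trajectory(states, sensors, symbols, length, seed)


@dataclass
class PluginEstimates:
    """Plug-in I_mem and I_pred with block-bootstrap standard errors (nats)."""

    memory: float
    memory_se: float
    predictive: float
    predictive_se: float
    n_samples: int


def _plugin_mi(counts: np.ndarray) -> float:
    total = counts.sum()
    q = counts / total
    a = q.sum(axis=1, keepdims=True)
    b = q.sum(axis=0, keepdims=True)
    mask = q > 0
    return float(np.sum(q[mask] * np.log(q[mask] / (a * b + 1e-300)[mask])))


def plugin_estimates(traj: Trajectory, burn_in: int = 1000,
                     block_length: int = 100, n_boot: int = 200,
                     seed: int | None = None) -> PluginEstimates:
    """Plug-in mutual-information estimates from a trajectory.

    Counts joint occurrences after ``burn_in`` steps; standard errors come
    from a block bootstrap (contiguous blocks of ``block_length`` steps,
    ``n_boot`` resamples) to respect serial dependence.
    """
    n = traj.length - burn_in
    if n < 100:
        raise ValueError("trajectory too short after burn-in (need >= 100 samples)")
    sig = traj.states[burn_in:]
    r = traj.sensor_states[burn_in:]
    x = traj.symbols[burn_in:]
    S = int(sig.max()) + 1
    N = int(r.max()) + 1
    A = int(x.max()) + 1

    nblocks = n // block_length
    n_used = nblocks * block_length
    mem_id = (r[:n_used] * S + sig[:n_used]).reshape(nblocks, block_length)
    pred_id = (r[:n_used] * A + x[:n_used]).reshape(nblocks, block_length)

    def block_hists(ids, ncat):
        h = np.zeros((nblocks, ncat))
        rows = np.repeat(np.arange(nblocks), block_length)
        np.add.at(h, (rows, ids.ravel()), 1.0)
        return h

    mem_h = block_hists(mem_id, N * S)
    pred_h = block_hists(pred_id, N * A)
    mem_mi = _plugin_mi(mem_h.sum(axis=0).reshape(N, S))
    pred_mi = _plugin_mi(pred_h.sum(axis=0).reshape(N, A))

    rng = np.random.default_rng(seed)
    boot_mem = np.empty(n_boot)
    boot_pred = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(nblocks, size=nblocks)
        boot_mem[b] = _plugin_mi(mem_h[pick].sum(axis=0).reshape(N, S))
        boot_pred[b] = _plugin_mi(pred_h[pick].sum(axis=0).reshape(N, A))
    return PluginEstimates(mem_mi, float(boot_mem.std(ddof=1)),
                           pred_mi, float(boot_pred.std(ddof=1)), n_used)
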