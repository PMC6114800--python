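"""Ensemble sweeps over sensor families and figure-level analyses.

A sweep fixes one environment, walks a grid of sensor parameters
(family, N, alpha, k), draws many random sensors per grid cell with
deterministically derived seeds, computes the exact metrics for each, and
records per-cell ensemble summaries (mean, median, interquartile band — the
50% confidence interval used for error bars).

On top of sweeps sit the scaling-law fit (log-log regression of the
ensemble mean against alpha*N), the fluctuation (IQR vs N) analysis, and the
feedforward null model (a memoryless Dirichlet read-out of the causal state,
whose information grows with the number of clusters N — the trend that
recurrent nondeterministic sensors fail to realize).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .machines import EpsilonMachine, environment_stats
from .metrics import sensor_metrics
from .sensors import dirichlet_sensor, heterogeneous_dirichlet_sensor, sparse_sensor

__all__ = [
    "SweepConfig",
    "SweepResult",
    "ScalingFit",
    "ensemble_sweep",
    "scaling_fit",
    "iqr_vs_size",
    "feedforward_null",
    "write_sweep",
    "read_sweep",
]

_COLUMNS = [
    "family", "N", "alpha", "k", "draws",
    "imem_mean", "imem_median", "imem_q25", "imem_q75",
    "ipred_mean", "ipred_median", "ipred_q25", "ipred_q75",
    "ipred_over_rho", "imem_over_cmu",
    "rho_mu", "c_mu", "n_failed",
]


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-draw seed from the master seed and cell coordinates."""
    ss = np.random.SeedSequence([int(master_seed), *[int(v) for v in key]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SweepConfig:
    """Grid description for an ensemble sweep over one environment.

    ``family`` is one of ``dirichlet``, ``heterogeneous`` or ``sparse``;
    ``k_values`` applies only to the sparse family (use ``[None]`` otherwise).
    """

    machine: EpsilonMachine
    family: str
    N_values: Sequence[int]
    alpha_values: Sequence[float]
    k_values: Sequence[int | None] = (None,)
    draws: int = 100
    master_seed: int = 0

    def __post_init__(self):
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        if not self.N_values or not self.alpha_values or not self.k_values:
            raise ValueError("parameter grids must be non-empty")
        if self.family not in ("dirichlet", "heterogeneous", "sparse"):
            raise ValueError(f"unknown sensor family {self.family!r}")


@dataclass
class SweepResult:
    """Per-cell ensemble summaries as a tidy table (one row per grid cell)."""

    records: pd.DataFrame
    config: SweepConfig | None = None


@dataclass
class ScalingFit:
    """Power-law fit ``mean_metric ~ prefactor * (alpha N)^exponent``."""

    exponent: float
    prefactor: float
    predictor_range: tuple[float, float]
    residual: float


def _make_sensor(family: str, N: int, alpha: float, k: int | None, seed: int):
    if family == "dirichlet":
        return dirichlet_sensor(N, alpha, seed=seed)
    if family == "heterogeneous":
        return heterogeneous_dirichlet_sensor(N, alpha, seed=seed)
    if family == "sparse":
        return sparse_sensor(N, k, alpha, seed=seed)
    raise ValueError(f"unknown sensor family {family!r}")


def ensemble_sweep(config: SweepConfig) -> SweepResult:
    """Run the sweep; deterministic given the master seed.

    Failed draws (e.g. steady-state non-convergence) are excluded from the
    cell summaries and counted in ``n_failed`` rather than silently dropped.
    """
    env = environment_stats(config.machine)
    rho, cmu = env.total_correlation_rate, env.statistical_complexity
    rows = []
    cell = 0
    for N in config.N_values:
        for alpha in config.alpha_values:
            for k in config.k_values:
                imem = []
                ipred = []
                failed = 0
                for d in range(config.draws):
                    seed = derive_seed(config.master_seed, cell, d)
                    try:
                        sensor = _make_sensor(config.family, N, alpha, k, seed)
                        m = sensor_metrics(config.machine, sensor, env=env)
                    except Exception:
                        failed += 1
                        continue
                    imem.append(m.memory)
                    ipred.append(m.predictive)
                cell += 1
                imem = np.array(imem)
                ipred = np.array(ipred)
                if imem.size == 0:
                    continue
                rows.append({
                    "family": config.family, "N": N, "alpha": alpha,
                    "k": -1 if k is None else k, "draws": imem.size,
                    "imem_mean": imem.mean(), "imem_median": np.median(imem),
                    "imem_q25": np.percentile(imem, 25), "imem_q75": np.percentile(imem, 75),
                    "ipred_mean": ipred.mean(), "ipred_median": np.median(ipred),
                    "ipred_q25": np.percentile(ipred, 25), "ipred_q75": np.percentile(ipred, 75),
                    "ipred_over_rho": ipred.mean() / rho if rho > 0 else np.nan,
                    "imem_over_cmu": imem.mean() / cmu if cmu > 0 else np.nan,
                    "rho_mu": rho, "c_mu": cmu, "n_failed": failed,
                })
    return SweepResult(pd.DataFrame(rows, columns=_COLUMNS), config)


def scaling_fit(result: SweepResult, metric: str = "imem",
                min_alpha_n: float = 10.0) -> ScalingFit:
    """Fit ``ln(mean metric) = ln(prefactor) + exponent * ln(alpha N)``.

    Uses only cells with ``alpha * N >= min_alpha_n`` (the asymptotic regime).
    """
    df = result.records
    col = {"imem": "imem_mean", "ipred": "ipred_mean"}.get(metric, metric)
    an = df["alpha"].to_numpy(float) * df["N"].to_numpy(float)
    y = df[col].to_numpy(float)
    keep = (an >= min_alpha_n) & (y > 0)
    if np.unique(an[keep]).size < 3:
        raise ValueError("need >= 3 distinct alpha*N values with alpha*N >= "
                         f"{min_alpha_n} for a scaling fit")
    lx, ly = np.log(an[keep]), np.log(y[keep])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = float(np.sqrt(np.mean((ly - (slope * lx + intercept)) ** 2)))
    return ScalingFit(float(slope), float(np.exp(intercept)),
                      (float(an[keep].min()), float(an[keep].max())), resid)


def iqr_vs_size(result: SweepResult, metric: str = "ipred") -> pd.DataFrame:
    """Interquartile range of the metric per sensor size N."""
    df = result.records
    if df["N"].nunique() < 2:
        raise ValueError("need >= 2 sensor sizes for the fluctuation analysis")
    q25, q75 = f"{metric}_q25", f"{metric}_q75"
    out = df[["N"]].copy()
    out["iqr"] = df[q75] - df[q25]
    return out.groupby("N", as_index=False)["iqr"].mean()


def feedforward_null(machine: EpsilonMachine, N: int, alpha: float,
                     draws: int = 100, seed: int | None = None) -> float:
    """Mean next-symbol information of a memoryless random soft clustering.

    Each draw assigns every causal state an independent Dirichlet(alpha 1_N)
    read-out distribution ``p(r | sigma)`` (a feedforward sensor with no
    recurrence); the returned value is the mean over draws of
    ``I[R; X_next]`` under ``p(r, sigma, x) = p_ss(sigma) p(r|sigma) Pr(x|sigma)``.
    Unlike the recurrent ensembles, this information grows with N.
    """
    from .metrics import mutual_information
    from .machines import stationary_distribution

    if N < 1:
        raise ValueError("N must be >= 1")
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    rng = np.random.default_rng(seed)
    p = stationary_distribution(machine)
    e = machine.emission  # (x, sigma)
    w = e * p  # (x, sigma): p(sigma, x)
    vals = np.empty(draws)
    for d in range(draws):
        readout = rng.dirichlet(np.full(N, alpha), size=machine.num_states).T  # (r, sigma)
        joint_rx = readout @ w.T  # (r, x)
        vals[d] = mutual_information(joint_rx)
    return float(vals.mean())


def write_sweep(result: SweepResult, path) -> None:
    """Persist the per-cell table as CSV with a header."""
    result.records.to_csv(path, index=False)


def read_sweep(path) -> SweepResult:
    """Read a persisted sweep table; columns are matched by header name."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed sweep file {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sweep file {path} is missing columns {missing}")
    return SweepResult(df[_COLUMNS], None)
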