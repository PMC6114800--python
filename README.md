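# predsensor

Can a randomly wired recurrent sensor predict its input just by being big?
`predsensor` is a library for studying that question quantitatively: it
generates random, partially predictable environments (binary-alphabet
unifilar hidden Markov models, i.e. ε-machines), wires up finite-state
stochastic sensors that watch the symbol stream, and computes *exactly* how
much the sensor's state knows about the environment and about the next
symbol. It is aimed at researchers in computational mechanics, reservoir
computing and biological sensing who want reproducible ensemble experiments
over random sensor wirings.

## The model

The environment is a unifilar HMM with causal states σ and labeled
transition matrices

    T^(x)[σ', σ] = Pr(S_{t+1} = σ', X_t = x | S_t = σ),

where the current state and emitted symbol uniquely determine the next
state. Its predictability is summarized by the statistical complexity
C_μ = H[S] (memory needed to predict optimally) and the total correlation
rate ρ_μ = I[past; X_next] (the ceiling on one-step predictive
information). Random environments draw each state's emission probability
uniformly on (0, 1) and uniform random successor states per symbol.

The sensor is a conditionally Markovian chain over N states driven by the
symbols: p(r_{t+1}) = M^(x_t) p(r_t) with column-stochastic M^(x). The pair
(σ_t, r_t) is itself a Markov chain whose stationary distribution
p_ss(σ, r) — the eigenvector of eigenvalue 1 of
Σ_x T^(x) ⊗ M^(x) — yields every metric in closed form:

* memory I_mem = I[R; S] ≤ C_μ,
* predictive information I_pred = I[R; X_next] ≤ min(I_mem, ρ_μ),
* the nonspecificity bound I′_mem = D_KL[p_ss(r, σ) ‖ p_ss(σ)/N] ≥ I_mem.

Sensor families: dense Dirichlet(α) random wirings, per-column
heterogeneous-α wirings, sparse k-destination (near-deterministic) wirings,
the optimal ε-machine sensor, and sensors optimized by L-BFGS with an exact
adjoint gradient. All informations are in nats.

## Worked example

```python
import predsensor as ps

m = ps.random_epsilon_machine(30, seed=3)
env = ps.environment_stats(m)
print(f"C_mu = {env.statistical_complexity:.3f} nats, "
      f"rho_mu = {env.total_correlation_rate:.3f} nats")

for label, s in [
    ("dense Dirichlet (N=64, alpha=3)", ps.dirichlet_sensor(64, 3.0, seed=0)),
    ("sparse k=1      (N=64, alpha=3)", ps.sparse_sensor(64, 1, 3.0, seed=0)),
    ("optimal (epsilon-machine copy)", ps.optimal_sensor(m)),
]:
    met = ps.sensor_metrics(m, s, env=env)
    print(f"{label}: I_mem {met.memory:.4f}  I_pred {met.predictive:.5f} "
          f"({100 * met.predictive_ratio:.1f}% of rho_mu)")
```

prints

```
C_mu = 2.887 nats, rho_mu = 0.218 nats
dense Dirichlet (N=64, alpha=3): I_mem 0.0007  I_pred 0.00000 (0.0% of rho_mu)
sparse k=1      (N=64, alpha=3): I_mem 0.5343  I_pred 0.01844 (8.5% of rho_mu)
optimal (epsilon-machine copy): I_mem 2.8874  I_pred 0.21776 (100.0% of rho_mu)
```

The environment needs ~2.9 nats of state memory and offers 0.218 nats of
one-step predictability. A large, fully random (dense Dirichlet) sensor is
nonspecific: it captures essentially nothing. The same-size sensor with
deterministic wiring (one destination per state and symbol, k = 1) captures
8.5% of the possible predictive information, and the ε-machine copy
saturates the bound exactly. Optimizing a small 10-state sensor directly,

```python
res = ps.optimize_sensor(m, 10, restarts=5, max_iter=100, seed=1)
```

reaches I_pred ≈ 0.030 nats (≈ 14% of ρ_μ) on this environment — random
near-deterministic wiring is competitive with local optimization.

Ensemble experiments run through `SweepConfig`/`ensemble_sweep`, with
`scaling_fit` (log-log fits of mean metrics against αN), `iqr_vs_size`
(fluctuation analysis) and `feedforward_null` (memoryless soft-clustering
null model). Monte Carlo cross-checks live in `simulate`/`plugin_estimates`.
A `predsensor` command-line tool wraps all of the above
(`predsensor --help`); machines and sensors serialize to JSON, sweep
results to CSV.

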