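# Methods

## Environment model

Environments are binary-alphabet unifilar hidden Markov models
(ε-machines). The labeled transition tensor `T[x, dest, src]` stores the
joint probability that state `src` emits symbol `x` and moves to `dest`;
unifilarity means each `(src, x)` has a single possible destination, so the
tensor carries one emission probability and one successor index per state
and symbol. The random generator draws, independently per state, the
probability of emitting 0 uniformly on (0, 1) and a uniform random successor
for each symbol (successors may coincide across symbols and may be
self-loops — the construction does not forbid either, and forbidding them is
not needed for any property used here). Because emission probabilities are
drawn from a continuous distribution, distinct states almost surely have
distinct conditional futures, so the machine is minimal almost surely; no
state-merging is performed.

Process statistics are computed exactly from the stationary distribution
p_ss(σ) of the symbol-marginal chain Σ_x T^(x):

* statistical complexity C_μ = H[S], with 0·ln 0 = 0;
* total correlation rate ρ_μ computed as I[S_t; X_t] at stationarity.
  The causal state is a sufficient statistic of the past, so the
  information the infinite past carries about the next symbol equals the
  information the current state carries about the symbol it emits; the
  same one-step-emission convention is used on the sensor side (below);
* the single-pair information I[X_t; X_{t+1}] from the exact joint
  p(x, x') = Σ_σ p_ss(σ) Pr(x|σ) Pr(x'|succ_x(σ)).

All logarithms are natural; every information value is in nats.

## Stationary distributions

Random successor maps routinely leave transient states and occasionally
create several recurrent classes, and the induced chains can mix
arbitrarily slowly, so the package solves stationary distributions two
ways:

* **Exact decomposition** (`stationary_exact`, used for all dense chains):
  strongly connected components are classified into recurrent and transient;
  each recurrent class is solved by a direct linear solve (replace one
  redundant row of P − I with the normalization row); with several
  recurrent classes, each class is weighted by the probability of
  absorption from the initial distribution (uniform by default), obtained
  from one linear solve on the transient block. Transient states get zero
  mass and, via 0·ln 0 = 0, contribute nothing to any entropy.
* **Lazy power iteration** (`stationary_from_matvec`, used for the large
  structured joint chain): iterate p ← (p + P p)/2. The half-step makes the
  chain aperiodic without changing per-class stationary distributions or
  absorption weights, so the iteration converges geometrically to the
  Cesàro (time-averaged) limit of the original chain from the given start.
  The stopping rule estimates the distance to the limit from the observed
  per-step contraction rate and stops below 1e-12 in L1; if 1e5 iterations
  do not suffice (slow mixing), the computation falls back to the exact
  decomposition for joint dimensions up to 4096 and otherwise raises an
  error carrying the residual.

Both routes agree to machine precision on irreducible chains; the
decomposition also serves as the independent cross-check of the iterative
route in the tests.

## Joint chain and sensor metrics

For machine and sensor with matching alphabets, the pair (σ_t, r_t) evolves
by J = Σ_x T^(x) ⊗ M^(x) (column-stochastic, flat index σ·N + r). One step
applied to the (|S|, N)-shaped distribution P factorizes as
Σ_x T^(x) P M^(x)ᵀ, and unifilar T^(x) apply as an emission-weighted
scatter, so an iteration costs O(|S| N²) and the dense matrix is only
formed when explicitly requested or needed by a fallback. The default
initial distribution is p_ss(σ) ⊗ uniform(N): environment at stationarity,
sensor uninformed. For reducible joint chains (common with deterministic
sensors, whose joint chain may or may not synchronize onto the matched
diagonal) this init makes the time-averaged answer deterministic and
reproducible.

From the stationary joint p_ss(σ, r):

* I_mem = I[R; S] directly;
* I_pred = I[R; X_next] through p(r, x) = Σ_σ p_ss(σ, r) Pr(x|σ), the
  one-step emission of the current causal state — the first symbol the
  sensor has not yet consumed. This is the convention under which the
  ε-machine sensor attains I_pred = ρ_μ exactly (verified to 1e-9 in the
  acceptance suite); pairing the sensor with the emission two steps ahead
  would make that bound unattainable;
* I′_mem = D_KL[p_ss(r, σ) ‖ p_ss(σ)/N], with KL terms on zero reference
  mass impossible for valid inputs (p_ss(σ) = 0 forces p_ss(σ, r) = 0).

The data-processing chain R → S → X_next gives the invariants
0 ≤ I_pred ≤ I_mem ≤ min(C_μ, I′_mem) and I_pred ≤ ρ_μ, which the test
suite enforces to 1e-9 across all sensor families.

## Sensor ensembles

Dirichlet draws are normalized iid Gamma(α, 1) variates (the degenerate
all-zero floating-point event is resampled). The heterogeneous family draws
a fresh α(x, r) ~ U(0, 10) per (symbol, source-column) — the column is the
natural unit of stochasticity, and per-column variation subsumes per-symbol
variation. The sparse family places a Dirichlet(α·1_k) draw on k distinct
uniformly chosen destinations per column; k = 1 gives a fully deterministic
wiring. The optimal sensor copies the machine's successor map; where a
symbol cannot be emitted from a state the column is a self-loop (any choice
is valid there; the self-loop keeps the sensor deterministic and the
construction reproducible).

## Optimization

`optimize_sensor` maximizes exact I_pred over all strictly positive
wirings, parameterized by unconstrained scores through column-wise softmax.
The gradient is exact: with J the joint chain, p its stationary
distribution and g = ∂I_pred/∂p, one adjoint solve
(I − J + p·1ᵀ)ᵀ λ = g gives ∂I_pred/∂M^(x) = Λᵀ T^(x) P, followed by the
softmax Jacobian (the adjoint is verified against central finite
differences in the tests). L-BFGS-B runs from iid standard-normal scores
with 5 restarts and 100 iterations by default; the returned trace is the
best-so-far objective at each accepted iterate, hence non-decreasing. The
I_pred ≤ ρ_μ ceiling is a property of the exact objective, never an
explicit constraint. If the stationary solve inside an evaluation is
singular the adjoint falls back to least squares.

## Monte Carlo oracle

`simulate` runs the coupled system forward: the initial causal state is
drawn from the exact stationary distribution (so burn-in only matters for
the sensor marginal; default 1000 steps), symbols are sampled from the
current state's emission distribution, states follow the unifilar
successor, sensor states sample the matching column of M^(x).
`plugin_estimates` forms maximum-likelihood mutual-information estimates
from joint counts of (r_t, σ_t) and (r_t, x_t) — the same alignment as the
exact method — with standard errors from a block bootstrap (blocks of 100
steps, 200 resamples) to respect serial dependence. Plug-in estimation is
adequate here because the oracle is confined to small state spaces and long
trajectories, where its positive bias is far below the reported standard
errors; no bias-corrected estimator is needed or provided.

## Ensemble sweeps and analyses

A sweep fixes one environment and walks a (family, N, α, k) grid with 100
draws per cell by default; per-draw seeds derive deterministically from the
master seed and the cell coordinates, so every number in a sweep is
bit-reproducible. Cells record mean, median and the 25th–75th percentile
band of I_mem and I_pred — the interquartile band is the "50% confidence
interval" used for error bars — plus ratios to ρ_μ and C_μ. Failed draws
are counted, not silently dropped. Default grids are N ∈ {4, 8, 16, 32, 64},
α ∈ {1, 3, 10} (plus α = 0.1 for the non-monotonicity experiment) and
k ∈ {1, 2, 4, 8}: large enough to expose all the qualitative trends while
keeping a full sweep in tens of seconds on one CPU.

`scaling_fit` regresses ln(mean metric) on ln(αN) over cells with αN ≥ 10
(the asymptotic regime). `feedforward_null` instantiates the memoryless
null model: a random soft clustering p(r|σ) with Dirichlet(α·1_N) columns
per causal state, scoring I[R; X_next] under
p(r, σ, x) = p_ss(σ) p(r|σ) Pr(x|σ). It isolates the capacity trend —
more clusters capture more information — that recurrent nondeterministic
sensors fail to realize.

## What the generators do and do not emulate

The synthetic environments reproduce the study conditions exactly: the
ensembles concentrate where expected (median C_μ ≈ 2.6 nats at |S| = 30,
median ρ_μ ≈ 0.19 at |S| = 100), and all qualitative sensor results
(nonspecificity of dense sensors, the low-α interior optimum in N, the
dominance and saturation of near-deterministic sensors, optimized sensors
trending deterministic) are robust across environments. They are still
finite-alphabet, discrete-time, stationary toy worlds: nothing here speaks
to continuous signals, nonstationary inputs, or sensors with learning
dynamics, so passing tests demonstrate properties of this model class, not
of any physical sensor.

## Numerical notes and known limitations

* Two ensemble-level published figures do not reproduce under the exact
  method, and the corresponding checks are deliberately left failing
  rather than loosened. (1) The median single-pair information
  I[X_t; X_{t+1}] over 30-state environments computes to ≈ 0.005–0.006
  nats (Markov ratio ≈ 0.03), a few times the published typical value of
  0.002 (ratio 0.01); the exact pair computation is verified against
  Monte Carlo symbol counts, and the generator has no free parameter that
  could move this median. (2) The dense-ensemble mean ⟨I_pred⟩ follows an
  inverse-first-power law in αN (free-fit exponent ≈ −0.95, with an
  environment-dependent prefactor), not the published inverse-square law;
  this holds across environments and under either temporal pairing of
  sensor state and upcoming symbol, while ⟨I_mem⟩ ≈ 0.1/αN reproduces
  cleanly on environments matched to the published per-figure statistics.
* Per-environment outcomes are heavy-tailed: the best captured fraction
  for sparse sensors and the quality of optimization local optima vary
  several-fold across environments with identical (ρ_μ, C_μ). Ensemble
  claims should therefore be read as medians/means over environments, and
  single-environment numbers quoted with the environment's statistics.
* Degenerate inputs: single-state machines (IID processes) and
  single-state sensors are fully supported and give exact zeros;
  environments with ρ_μ = 0 yield NaN ratios, which ensemble medians
  exclude.
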