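"""Exact information metrics and the joint-chain eigenvector method."""

import numpy as np
import pytest

from predsensor import (
    StationaryJoint,
    dirichlet_sensor,
    entropy,
    environment_stats,
    heterogeneous_dirichlet_sensor,
    joint_transition,
    memory_information,
    memory_kl_bound,
    mutual_information,
    optimal_sensor,
    predictive_distribution,
    predictive_information,
    random_epsilon_machine,
    sensor_metrics,
    sparse_sensor,
    steady_state_joint,
)


@pytest.mark.parametrize("dist,expected", [
    ([0.5, 0.5], np.log(2)),
    ([1.0, 0.0], 0.0),
    ([0.25, 0.75], 0.562335),  # -0.25 ln 0.25 - 0.75 ln 0.75
])
def test_entropy_values(dist, expected):
    assert entropy(dist) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize("bad", [[0.6, 0.6], [-0.1, 1.1], [0.5, 0.4]])
def test_entropy_rejects_bad_distributions(bad):
    with pytest.raises(ValueError):
        entropy(bad)


@pytest.mark.parametrize("joint,expected", [
    (np.outer([0.3, 0.7], [0.2, 0.8]), 0.0),
    (np.diag([0.5, 0.5]), np.log(2)),
    (np.array([[0.4, 0.1], [0.1, 0.4]]), 0.192745),  # direct evaluation
])
def test_mutual_information_values(joint, expected):
    assert mutual_information(joint) == pytest.approx(expected, abs=1e-6)


def test_joint_chain_columns_stochastic(small_machine):
    s = dirichlet_sensor(4, 1.0, seed=1)
    J = joint_transition(small_machine, s).matrix
    np.testing.assert_allclose(J.sum(axis=0), 1.0, atol=1e-12)
    assert np.all(J >= 0) and np.all(J <= 1)


def test_joint_chain_alphabet_mismatch_rejected(small_machine):
    s = dirichlet_sensor(3, 1.0, alphabet_size=3, seed=0)
    with pytest.raises(ValueError, match="alphabet"):
        joint_transition(small_machine, s)


def test_index_map_round_trip(small_machine):
    chain = joint_transition(small_machine, dirichlet_sensor(4, 1.0, seed=0))
    for i in range(chain.dim):
        sigma, r = chain.pair_of(i)
        assert chain.flat_index(sigma, r) == i


def test_structured_step_matches_dense_matrix(small_machine):
    s = sparse_sensor(4, 2, 3.0, seed=2)
    chain = joint_transition(small_machine, s)
    rng = np.random.default_rng(0)
    P = rng.dirichlet(np.ones(chain.dim)).reshape(5, 4)
    np.testing.assert_allclose(chain.step(P).ravel(), chain.matrix @ P.ravel(), atol=1e-13)


def test_trivial_sensor_reduces_to_environment(small_machine):
    """An N=1 sensor leaves the joint chain equal to the state chain and
    carries zero information."""
    s = dirichlet_sensor(1, 1.0, seed=0)
    chain = joint_transition(small_machine, s)
    np.testing.assert_allclose(chain.matrix, small_machine.symbol_marginal_chain, atol=1e-13)
    sj = steady_state_joint(chain)
    from predsensor import stationary_distribution
    np.testing.assert_allclose(sj.p[:, 0], stationary_distribution(small_machine), atol=1e-9)
    assert memory_information(sj) == pytest.approx(0.0, abs=1e-12)
    assert predictive_information(small_machine, s) == pytest.approx(0.0, abs=1e-12)


def test_steady_state_properties(medium_machine):
    from predsensor import stationary_distribution
    s = heterogeneous_dirichlet_sensor(6, 10.0, seed=3)
    sj = steady_state_joint(joint_transition(medium_machine, s))
    assert np.all(sj.p >= 0)
    assert abs(sj.p.sum() - 1.0) < 1e-10
    np.testing.assert_allclose(sj.p_sigma, stationary_distribution(medium_machine), atol=1e-8)


def test_steady_state_matches_simulation_counts():
    from predsensor import simulate

    m = random_epsilon_machine(5, seed=8)
    s = dirichlet_sensor(4, 1.0, seed=8)
    sj = steady_state_joint(joint_transition(m, s))
    traj = simulate(m, s, 300_000, seed=10)
    counts = np.zeros((5, 4))
    np.add.at(counts, (traj.states, traj.sensor_states), 1.0)
    freq = counts / counts.sum()
    se = np.sqrt(np.maximum(sj.p * (1 - sj.p) / counts.sum(), 1e-12))
    assert np.all(np.abs(freq - sj.p) < 5 * se + 1e-3)


def test_optimal_sensor_preserves_matched_diagonal(medium_machine):
    """Once sensor state equals causal state, the coupled dynamics keep them
    equal: columns of the joint chain at matched pairs have support only on
    matched pairs."""
    s = optimal_sensor(medium_machine)
    chain = joint_transition(medium_machine, s)
    J = chain.matrix
    S = medium_machine.num_states
    for sigma in range(S):
        col = J[:, chain.flat_index(sigma, sigma)]
        for i in np.nonzero(col)[0]:
            sig2, r2 = chain.pair_of(i)
            assert sig2 == r2


def test_memory_zero_for_product_joint():
    sj = StationaryJoint(np.outer([0.2, 0.8], [0.5, 0.3, 0.2]))
    assert memory_information(sj) == pytest.approx(0.0, abs=1e-12)
    assert memory_kl_bound(sj) > 0  # nonuniform sensor marginal still penalized


def test_memory_kl_bound_hand_computed():
    p = np.array([[0.3, 0.2], [0.25, 0.25]])
    sj = StationaryJoint(p)
    q = p.sum(axis=1)
    expected = sum(p[i, j] * np.log(p[i, j] / (q[i] / 2))
                   for i in range(2) for j in range(2))
    assert memory_kl_bound(sj, N=2) == pytest.approx(expected, abs=1e-12)


def test_memory_kl_bound_zero_for_uniform_conditional():
    p = np.outer([0.6, 0.4], [0.25, 0.25, 0.25, 0.25])
    assert memory_kl_bound(StationaryJoint(p)) == pytest.approx(0.0, abs=1e-12)


def test_predictive_distribution_consistency(medium_machine):
    s = dirichlet_sensor(5, 1.0, seed=4)
    sj = steady_state_joint(joint_transition(medium_machine, s))
    Q = predictive_distribution(sj, medium_machine)
    assert abs(Q.sum() - 1.0) < 1e-10
    # marginal over sensor states is the stationary symbol distribution
    np.testing.assert_allclose(Q.sum(axis=0),
                               medium_machine.emission @ sj.p_sigma, atol=1e-9)


@pytest.mark.parametrize("family", ["dirichlet", "hetero", "sparse", "optimal"])
def test_bound_chain_across_families(medium_machine, family):
    """0 <= I_pred <= I_mem <= min(C_mu, I'_mem), I_pred <= rho_mu."""
    env = environment_stats(medium_machine)
    for seed in range(25):
        if family == "dirichlet":
            s = dirichlet_sensor(2 + seed % 8, 10 ** ((seed % 5) - 2.0), seed=seed)
        elif family == "hetero":
            s = heterogeneous_dirichlet_sensor(2 + seed % 8, 10.0, seed=seed)
        elif family == "sparse":
            N = 2 + seed % 8
            s = sparse_sensor(N, 1 + seed % N, 3.0, seed=seed)
        else:
            s = optimal_sensor(medium_machine)
        met = sensor_metrics(medium_machine, s, env=env)
        assert -1e-12 <= met.predictive
        assert met.predictive <= met.memory + 1e-9
        assert met.memory <= env.statistical_complexity + 1e-9
        assert met.memory <= met.memory_kl_bound + 1e-9
        assert met.predictive <= env.total_correlation_rate + 1e-9


def test_nonspecificity_grows_with_alpha_n(medium_machine):
    """For fixed alpha >= 1, mean I_mem strictly decreases along N, and the
    conditional steady state approaches uniformity as alpha*N grows."""
    env = environment_stats(medium_machine)
    means = []
    unif_dev = []
    for N in (8, 32, 128):
        vals = []
        for d in range(15):
            s = dirichlet_sensor(N, 1.0, seed=100 * N + d)
            sj = steady_state_joint(joint_transition(medium_machine, s))
            vals.append(memory_information(sj))
            if d == 0:
                live = sj.p_sigma > 0
                cond = sj.p[live] / sj.p_sigma[live, None]
                unif_dev.append(np.abs(cond - 1.0 / N).sum(axis=1).max())
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]
    assert unif_dev[0] > unif_dev[2]
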