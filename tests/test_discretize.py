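import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from tsnet.datatypes import GeneStateMatrix
from tsnet.discretize import (
    HmmGmmModel,
    baseline_discretize,
    em_train,
    init_model,
    viterbi_decode,
)

from conftest import make_dataset


def random_model(rng, Q, sigma_range=(0.3, 1.5)) -> HmmGmmModel:
    pi = rng.dirichlet(np.ones(Q))
    A = rng.dirichlet(np.ones(Q), size=Q)
    mu = np.sort(rng.normal(0, 3, size=Q))[:, None]
    sigma = rng.uniform(*sigma_range, size=(Q, 1))
    return HmmGmmModel(Q, 1, pi, A, np.ones((Q, 1)), mu, sigma, 1e-6)


def brute_force_path(model, obs):
    """Exhaustive path search with independently computed emissions."""
    Q, T = model.Q, len(obs)
    best, best_ll = None, -np.inf
    for code in range(Q**T):
        path, c = [], code
        for _ in range(T):
            path.append(c % Q)
            c //= Q
        ll = np.log(model.pi[path[0]])
        for t in range(1, T):
            ll += np.log(model.A[path[t - 1], path[t]])
        for t, s in enumerate(path):
            ll += logsumexp(
                np.log(model.w[s]) + norm.logpdf(obs[t], model.mu[s], model.sigma[s])
            )
        if ll > best_ll:
            best_ll, best = ll, path
    return np.array(best) + 1, best_ll


def decode_single(model, obs):
    ds = make_dataset(np.asarray(obs, dtype=float).reshape(1, 1, -1))
    return viterbi_decode(model, ds)["P0"].states[0]


# ---------------------------------------------------------------------------
# initialization


def test_init_bins_mean_and_sd():
    ds = make_dataset(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4))
    m = init_model(ds, Q=2)
    np.testing.assert_allclose(m.mu[:, 0], [1.5, 3.5])
    np.testing.assert_allclose(m.sigma[:, 0], [0.7071, 0.7071], atol=1e-4)


def test_init_uniform_distributions():
    rng = np.random.default_rng(2)
    ds = make_dataset(rng.normal(size=(2, 4, 5)))
    m = init_model(ds, Q=3)
    np.testing.assert_allclose(m.pi, np.full(3, 1 / 3))
    np.testing.assert_allclose(m.A, np.full((3, 3), 1 / 3))
    np.testing.assert_allclose(m.w, np.full((3, 4), 1 / 4))


def test_init_q_exceeding_distinct_values_errors():
    ds = make_dataset(np.array([1.0, 1.0, 2.0, 2.0]).reshape(1, 1, 4))
    with pytest.raises(ValueError, match="distinct"):
        init_model(ds, Q=3)


# ---------------------------------------------------------------------------
# EM


def test_em_loglik_never_decreases(rng):
    ds = make_dataset(rng.normal(size=(3, 5, 6)))
    m = em_train(init_model(ds, Q=3), ds, max_iter=40)
    hist = np.array(m.loglik_history)
    assert len(hist) > 1
    assert np.all(np.diff(hist) >= -1e-8)


def test_em_zero_iterations_only_relabels(rng):
    ds = make_dataset(rng.normal(size=(2, 3, 5)))
    m0 = init_model(ds, Q=3)
    m = em_train(m0, ds, max_iter=0)
    # equal-count bins are already ordered by mean, so relabeling is a no-op
    np.testing.assert_array_equal(m.mu, m0.mu)
    np.testing.assert_array_equal(m.A, m0.A)
    m_inf = em_train(m0, ds, max_iter=50, tol=np.inf)
    np.testing.assert_array_equal(m_inf.mu, m0.mu)


def test_em_relabels_states_by_emission_mean(rng):
    ds = make_dataset(rng.normal(size=(3, 4, 6)))
    m = em_train(init_model(ds, Q=3), ds, max_iter=30)
    means = m.state_means
    assert np.all(np.diff(means) >= 0)


# ---------------------------------------------------------------------------
# Viterbi


def test_viterbi_matches_exhaustive_enumeration(rng):
    for _ in range(60):
        Q = int(rng.integers(2, 4))
        T = int(rng.integers(2, 7))
        model = random_model(rng, Q)
        obs = rng.normal(0, 3, size=T)
        expected, expected_ll = brute_force_path(model, obs)
        np.testing.assert_array_equal(decode_single(model, obs), expected)


def test_viterbi_single_state_trivial():
    model = HmmGmmModel(
        1, 1, np.ones(1), np.ones((1, 1)), np.ones((1, 1)),
        np.zeros((1, 1)), np.ones((1, 1)), 1e-6,
    )
    np.testing.assert_array_equal(decode_single(model, [0.3, -1.0, 2.0]), [1, 1, 1])


def test_viterbi_disjoint_emissions_follow_observations():
    # states at 0 and 100 with tiny sigma: observations dictate the path
    # regardless of a transition matrix that abhors switching
    A = np.array([[0.999, 0.001], [0.001, 0.999]])
    model = HmmGmmModel(
        2, 1, np.array([0.5, 0.5]), A, np.ones((2, 1)),
        np.array([[0.0], [100.0]]), np.full((2, 1), 0.1), 1e-6,
    )
    obs = [0.1, 100.2, 0.0, 99.8]
    np.testing.assert_array_equal(decode_single(model, obs), [1, 2, 1, 2])


# ---------------------------------------------------------------------------
# baseline discretizers


def test_average_row_uses_strict_greater():
    ds = make_dataset(np.array([1.0, 2.0, 3.0]).reshape(1, 1, 3))
    sm = baseline_discretize(ds, "average", scope="row")["P0"]
    np.testing.assert_array_equal(sm.states[0], [1, 1, 2])


def test_midrange_row_threshold():
    ds = make_dataset(np.array([0.0, 10.0, 4.0]).reshape(1, 1, 3))
    sm = baseline_discretize(ds, "midrange", scope="row")["P0"]
    np.testing.assert_array_equal(sm.states[0], [1, 2, 1])


def test_efp_all_equal_frequency():
    ds = make_dataset(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4))
    sm = baseline_discretize(ds, "efp", scope="all", Q=2)["P0"]
    np.testing.assert_array_equal(sm.states[0], [1, 1, 2, 2])


def test_top_x_marks_top_fraction():
    ds = make_dataset(np.array([5.0, 1.0, 4.0, 2.0]).reshape(1, 1, 4))
    sm = baseline_discretize(ds, "top_x", scope="row", x=50.0)["P0"]
    np.testing.assert_array_equal(sm.states[0], [2, 1, 2, 1])


def test_max_x_max_threshold():
    ds = make_dataset(np.array([10.0, 9.5, 5.0]).reshape(1, 1, 3))
    sm = baseline_discretize(ds, "max_x_max", scope="row", x=10.0)["P0"]
    np.testing.assert_array_equal(sm.states[0], [2, 2, 1])


def test_x_out_of_range_errors():
    ds = make_dataset(np.zeros((1, 1, 3)) + [[[1.0, 2.0, 3.0]]])
    for bad in (0.0, 100.0, -3.0):
        with pytest.raises(ValueError, match="x must be"):
            baseline_discretize(ds, "top_x", scope="row", x=bad)


def test_average_all_invariant_to_gene_order(rng):
    vals = rng.normal(size=(1, 5, 4))
    ds = make_dataset(vals)
    perm = rng.permutation(5)
    ds_perm = make_dataset(vals[:, perm], gene_ids=[f"g{j}" for j in perm])
    sm = baseline_discretize(ds, "average", scope="all")["P0"]
    sm_perm = baseline_discretize(ds_perm, "average", scope="all")["P0"]
    np.testing.assert_array_equal(sm.states[perm], sm_perm.states)
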