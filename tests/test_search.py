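import numpy as np
import pytest

from bmr import core, search
from bmr.core import FullModel
from bmr.gaussian import GaussianDensity

from conftest import random_full_model


def make_space(full, switchable=None, gamma=2.0, constraints=()):
    if switchable is None:
        switchable = tuple(range(full.dim))
    return search.SwitchSpace(
        base_prior=full.prior,
        switchable=tuple(switchable),
        gamma=gamma,
        constraints=tuple(constraints),
    )


def conjugate_regression_model(rng, p, support, n=200, gamma=2.0, noise_var=0.25):
    """Exact conjugate posterior of a linear regression with a diagonal
    N(0, gamma) prior and known noise; support lists the nonzero betas."""
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[list(support)] = 1.0
    y = X @ beta + rng.standard_normal(n) * np.sqrt(noise_var)
    prior = GaussianDensity.from_variances(np.zeros(p), np.full(p, gamma))
    post_prec = prior.precision + X.T @ X / noise_var
    post_mean = np.linalg.solve(post_prec, X.T @ y / noise_var)
    return FullModel(
        prior=prior, posterior=GaussianDensity(post_mean, post_prec)
    )


# --------------------------------------------------------------------- #
# model-space combinatorics
# --------------------------------------------------------------------- #
def test_counts_unconstrained(rng):
    full = random_full_model(rng, 12, diagonal_prior=True)
    space = make_space(full)
    assert space.n_free_switches == 12
    assert space.n_models == 4096
    assert len(search.enumerate_switches(space)) == 4096


def test_counts_bidirectional_pairs(rng):
    # 4 nodes -> 12 off-diagonal couplings in 6 reciprocal pairs -> 64 models
    full = random_full_model(rng, 12, diagonal_prior=True)
    pairs = tuple((2 * k, 2 * k + 1) for k in range(6))
    space = make_space(full, constraints=pairs)
    assert space.n_free_switches == 6
    assert space.n_models == 64
    vectors = search.enumerate_switches(space)
    assert len(vectors) == 64
    for lam in vectors:
        for a, b in ((2 * k, 2 * k + 1) for k in range(6)):
            ia = space.switchable.index(a)
            ib = space.switchable.index(b)
            assert lam[ia] == lam[ib]


def test_count_eight_node_adjacency_is_astronomical(rng):
    # 8 nodes -> 56 directed off-diagonal couplings in 28 reciprocal pairs
    # would still be enumerable; the unconstrained directed space with
    # self-connections is 2^64, about 1.84e19 models
    assert 2**64 == 18446744073709551616
    assert abs(2**64 / 1.84e19 - 1) < 0.01


def test_exhaustive_cap_enforced(rng):
    full = random_full_model(rng, 25, diagonal_prior=True)
    space = make_space(full)
    with pytest.raises(ValueError):
        search.enumerate_switches(space)


# --------------------------------------------------------------------- #
# scoring
# --------------------------------------------------------------------- #
def test_fast_scorer_matches_naive_reduce(rng):
    """The cached scorer must agree with scoring every model through
    core.reduce to floating-point accuracy."""
    full = conjugate_regression_model(rng, 6, support=[0, 1], n=40)
    space = make_space(full, gamma=2.0)
    result = search.exhaustive_search(full, space)
    for lam, df in zip(result.switch_vectors, result.delta_f):
        rp = search.prior_for_switches(space, lam)
        assert abs(df - core.reduce(full, rp).delta_f) < 1e-10


def test_fast_scorer_matches_naive_with_constraints_and_offsets(rng):
    full = random_full_model(rng, 5, diagonal_prior=True)
    space = make_space(full, switchable=(0, 2, 4), gamma=3.0, constraints=((0, 4),))
    result = search.exhaustive_search(full, space)
    assert space.n_models == 4
    for lam, df in zip(result.switch_vectors, result.delta_f):
        rp = search.prior_for_switches(space, lam)
        assert abs(df - core.reduce(full, rp).delta_f) < 1e-10


def test_posterior_probs_normalized(rng):
    full = conjugate_regression_model(rng, 5, support=[0], n=30)
    result = search.exhaustive_search(full, make_space(full))
    assert abs(result.posterior_probs.sum() - 1.0) < 1e-10
    assert result.best_index == int(np.argmax(result.delta_f))


def test_exhaustive_recovers_planted_support(rng):
    full = conjugate_regression_model(rng, 8, support=[1, 4], n=120)
    result = search.exhaustive_search(full, make_space(full))
    expect = tuple(int(k in (1, 4)) for k in range(8))
    assert result.best_switches == expect


# --------------------------------------------------------------------- #
# greedy search
# --------------------------------------------------------------------- #
def test_greedy_matches_exhaustive_winner(rng):
    for trial in range(5):
        p = 10
        support = list(rng.choice(p, size=3, replace=False))
        full = conjugate_regression_model(rng, p, support, n=80)
        space = make_space(full)
        ex = search.exhaustive_search(full, space)
        gr = search.greedy_search(full, space, block_size=4)
        assert gr.best_switches == ex.best_switches
        assert abs(gr.delta_f[gr.best_index] - ex.delta_f[ex.best_index]) < 1e-9


def test_greedy_recovers_support_beyond_exhaustive_reach(rng):
    p = 20
    support = [0, 5, 9, 13, 19]
    full = conjugate_regression_model(rng, p, support, n=400)
    space = make_space(full)
    assert space.n_models == 2**20
    gr = search.greedy_search(full, space, block_size=6)
    assert gr.best_switches == tuple(int(k in support) for k in range(p))


def test_greedy_respects_constraints(rng):
    full = conjugate_regression_model(rng, 8, support=[0, 1], n=100)
    pairs = tuple((2 * k, 2 * k + 1) for k in range(4))
    space = make_space(full, constraints=pairs)
    gr = search.greedy_search(full, space, block_size=2)
    for lam in gr.switch_vectors:
        for a, b in pairs:
            assert lam[space.switchable.index(a)] == lam[space.switchable.index(b)]
    assert gr.best_switches == (1, 1, 0, 0, 0, 0, 0, 0)


def test_search_determinism(rng):
    full = conjugate_regression_model(rng, 8, support=[2], n=60)
    space = make_space(full)
    a = search.exhaustive_search(full, space)
    b = search.exhaustive_search(full, space)
    assert a.best_switches == b.best_switches
    assert np.array_equal(a.delta_f, b.delta_f)
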