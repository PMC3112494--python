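import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from bmr import core, glm
from bmr.core import FullModel, InvalidReductionError, SupportError
from bmr.gaussian import GaussianDensity

from conftest import random_full_model, random_spd


# --------------------------------------------------------------------- #
# quadrature oracles for the reduced-evidence integral
# --------------------------------------------------------------------- #
def quad_delta_f_1d(full: FullModel, reduced_prior: GaussianDensity) -> float:
    """delta F = log integral of q(theta) p_r(theta) / p_f(theta)."""
    q = norm(full.posterior.mean[0], np.sqrt(full.posterior.covariance[0, 0]))
    pr = norm(reduced_prior.mean[0], np.sqrt(reduced_prior.covariance[0, 0]))
    pf = norm(full.prior.mean[0], np.sqrt(full.prior.covariance[0, 0]))
    val, _ = integrate.quad(
        lambda t: q.pdf(t) * pr.pdf(t) / pf.pdf(t), -30, 30, limit=400
    )
    return float(np.log(val))


def gh_delta_f(full: FullModel, reduced_prior: GaussianDensity, order=80) -> float:
    """Gauss-Hermite quadrature of the same integrand in d dimensions."""
    d = full.dim
    nodes, weights = np.polynomial.hermite_e.hermegauss(order)
    chol = np.linalg.cholesky(full.posterior.covariance)
    grids = np.meshgrid(*([nodes] * d), indexing="ij")
    z = np.stack([g.ravel() for g in grids])
    theta = full.posterior.mean[:, None] + chol @ z
    w = np.ones(z.shape[1])
    for k in range(d):
        w *= weights[np.searchsorted(nodes, z[k])]
    pr = multivariate_normal(reduced_prior.mean, reduced_prior.covariance)
    pf = multivariate_normal(full.prior.mean, full.prior.covariance)
    ratio = np.exp(pr.logpdf(theta.T) - pf.logpdf(theta.T))
    # expectation of the prior ratio under the posterior
    return float(np.log((w * ratio).sum()) - np.log(w.sum()))


def test_reduce_matches_1d_quadrature(rng):
    for _ in range(5):
        full = random_full_model(rng, 1)
        reduced_prior = GaussianDensity.from_variances(
            np.array([rng.uniform(-0.5, 0.5)]), np.array([rng.uniform(0.2, 1.5)])
        )
        res = core.reduce(full, reduced_prior)
        assert abs(res.delta_f - quad_delta_f_1d(full, reduced_prior)) < 1e-6


def test_reduce_matches_3d_quadrature(rng):
    full = random_full_model(rng, 3)
    reduced_prior = GaussianDensity.from_covariance(
        rng.standard_normal(3) * 0.2, random_spd(rng, 3, 0.3)
    )
    res = core.reduce(full, reduced_prior)
    assert abs(res.delta_f - gh_delta_f(full, reduced_prior)) < 1e-6


def test_reduce_identity_is_zero(rng):
    full = random_full_model(rng, 4)
    res = core.reduce(full, full.prior)
    assert abs(res.delta_f) < 1e-10
    assert np.allclose(res.posterior.mean, full.posterior.mean)
    assert np.allclose(res.posterior.precision, full.posterior.precision)


def test_clamp_is_savage_dickey_ratio(rng):
    """Clamping equals the posterior/prior marginal density ratio at the
    clamp point, and the reduced posterior is the full-posterior conditional."""
    full = random_full_model(rng, 4)
    idx = [1, 3]
    vals = [0.0, 0.25]
    res = core.clamp(full, idx, vals)
    i = np.array(idx)
    v = np.array(vals)
    expect = full.posterior.marginal_logpdf(i, v) - full.prior.marginal_logpdf(i, v)
    assert abs(res.delta_f - expect) < 1e-10
    cond = full.posterior.condition(i, v)
    keep = np.array([0, 2])
    assert np.allclose(res.posterior.mean[keep], cond.mean)
    assert res.posterior.point_mass[i].all()


def test_clamp_equals_epsilon_variance_limit(rng):
    """Shrinking one prior variance to eps converges to the point-mass clamp."""
    full = random_full_model(rng, 3, diagonal_prior=True)
    idx, val = 1, 0.4
    exact = core.clamp(full, [idx], [val]).delta_f
    var = full.prior.variances.copy()
    mean = full.prior.mean.copy()
    eps = 1e-6 * var[idx]
    var[idx] = eps
    mean[idx] = val
    reduced = GaussianDensity.from_variances(mean, var)
    approx = core.reduce(full, reduced).delta_f
    assert abs(approx - exact) < 1e-3


def test_reduce_matches_conjugate_evidence_differences(rng):
    """On a conjugate linear-Gaussian model, BMR reproduces exact
    log-evidence differences between priors to < 1e-8 nats."""
    n, p = 24, 4
    X = rng.standard_normal((n, p))
    beta = np.array([1.0, -0.5, 0.0, 0.0])
    noise_var = 0.5
    y = X @ beta + rng.standard_normal(n) * np.sqrt(noise_var)
    data = glm.GLMData(y=y, X=X)
    prior_f = GaussianDensity.from_variances(np.zeros(p), np.full(p, 4.0))
    # exact conjugate posterior under the full prior
    post_prec = prior_f.precision + X.T @ X / noise_var
    post_mean = np.linalg.solve(post_prec, X.T @ y / noise_var)
    full = FullModel(
        prior=prior_f,
        posterior=GaussianDensity(post_mean, post_prec),
        free_energy=glm.closed_form_evidence(data, prior_f, np.array([noise_var])),
    )
    for variances in ([4.0, 4.0, 0.5, 0.5], [1.0, 4.0, 4.0, 2.0]):
        prior_r = GaussianDensity.from_variances(np.zeros(p), np.array(variances))
        res = core.reduce(full, prior_r)
        exact = glm.closed_form_evidence(data, prior_r, np.array([noise_var]))
        assert abs((full.free_energy + res.delta_f) - exact) < 1e-8


def test_tighter_clamp_away_from_posterior_mode_loses_evidence(rng):
    """Moving the clamp point away from the posterior mean monotonically
    lowers the reduced evidence (Mahalanobis monotonicity)."""
    prior = GaussianDensity.from_variances(np.zeros(2), np.array([2.0, 2.0]))
    post = GaussianDensity.from_covariance(
        np.zeros(2), np.array([[0.5, 0.1], [0.1, 0.4]])
    )
    full = FullModel(prior=prior, posterior=post)
    deltas = [0.0, 0.5, 1.0, 2.0, 4.0]
    dfs = [core.clamp(full, [0], [d]).delta_f for d in deltas]
    assert all(a > b for a, b in zip(dfs, dfs[1:]))


def test_invalid_reduction_raises_with_label():
    prior = GaussianDensity.from_variances(np.zeros(1), np.array([1.0]), ("slope",))
    post = GaussianDensity.from_variances(np.array([0.3]), np.array([1.2]), ("slope",))
    full = FullModel(prior=prior, posterior=post)
    wide = GaussianDensity.from_variances(np.zeros(1), np.array([100.0]), ("slope",))
    with pytest.raises(InvalidReductionError, match="slope"):
        core.reduce(full, wide)


def test_support_error_on_relaxing_point_mass():
    prior = GaussianDensity.from_variances(np.zeros(2), np.array([1.0, 0.0]))
    post_prec = np.zeros((2, 2))
    post_prec[0, 0] = 2.0
    post = GaussianDensity(
        np.array([0.1, 0.0]), post_prec, point_mass=np.array([False, True])
    )
    full = FullModel(prior=prior, posterior=post)
    relaxed = GaussianDensity.from_variances(np.zeros(2), np.array([1.0, 1.0]))
    with pytest.raises(SupportError):
        core.reduce(full, relaxed)


def test_model_posterior_properties(rng):
    f = rng.standard_normal(6) * 10
    p = core.model_posterior(f)
    assert abs(p.sum() - 1.0) < 1e-12
    assert (p > 0).all()
    assert np.allclose(p, core.model_posterior(f + 123.4))
    assert np.argmax(p) == np.argmax(f)


def test_pool_subjects_is_row_sum_and_reweights_winner():
    # rows are models, columns are subjects: model 1 wins in three of four
    # subjects but loses decisively in the last; fixed-effects pooling picks
    # the model with the best total evidence
    per_model = np.array(
        [[0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, -9.0]]
    )
    pooled = core.pool_subjects(per_model)
    assert np.allclose(pooled, per_model.sum(axis=1))
    assert np.argmax(pooled) == 0
    # per-subject majority view would have picked model 1
    assert np.argmax(np.sum(per_model > 0, axis=1)) == 1
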