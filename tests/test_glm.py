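import numpy as np
import pytest

from bmr import core, glm
from bmr.gaussian import GaussianDensity


# --------------------------------------------------------------------- #
# simulators
# --------------------------------------------------------------------- #
def test_optimization_dataset_shape_and_determinism():
    data, truth = glm.simulate_optimization_dataset(7)
    again, _ = glm.simulate_optimization_dataset(7)
    other, _ = glm.simulate_optimization_dataset(8)
    assert data.n == 64 and data.p == 4 and data.n_groups == 2
    assert np.array_equal(data.y, again.y) and np.array_equal(data.X, again.X)
    assert not np.array_equal(data.y, other.y)
    assert np.allclose(truth["beta"], 1.0)
    assert np.allclose(truth["logprec"], [2.0, 1.0])


def test_optimization_dataset_noiseless_limit():
    data, _ = glm.simulate_optimization_dataset(3, noise_scale=0.0)
    assert np.allclose(data.y, data.X @ np.ones(4))


def test_selection_dataset_structure():
    data, truth = glm.simulate_selection_dataset(11)
    assert data.n == 16 and data.p == 12 and data.n_groups == 1
    assert truth["support"] == [0, 1, 2, 3]
    clean, _ = glm.simulate_selection_dataset(11, noise_scale=0.0)
    assert np.allclose(clean.y, clean.X[:, :4].sum(axis=1))


def test_selection_noise_matches_stated_precision():
    # pooled over seeds, the residual variance must match 1/precision = 0.5
    resid = []
    for seed in range(200):
        data, truth = glm.simulate_selection_dataset(seed)
        resid.extend(data.y - data.X[:, :4].sum(axis=1))
    v = np.var(resid)
    assert abs(v - 0.5) < 0.03


# --------------------------------------------------------------------- #
# variational-Laplace inversion
# --------------------------------------------------------------------- #
def test_invert_free_energy_monotone_and_converged():
    for seed in (0, 1, 2):
        data, _ = glm.simulate_optimization_dataset(seed)
        fm = glm.invert(data, glm.default_priors(data.p, data.n_groups))
        hist = np.array(fm.meta["f_history"])
        assert fm.meta["converged"]
        assert np.all(np.diff(hist) > -1e-9)
        assert fm.free_energy == pytest.approx(hist.max())


def test_invert_labels_and_block_structure():
    data, _ = glm.simulate_optimization_dataset(0)
    fm = glm.invert(data, glm.default_priors(4, 2))
    assert fm.posterior.labels == (
        "beta_0", "beta_1", "beta_2", "beta_3", "logprec_1", "logprec_2"
    )
    # mean-field: no posterior coupling between coefficients and precisions
    assert np.allclose(fm.posterior.precision[:4, 4:], 0.0)


def test_invert_recovers_coefficients_and_precisions():
    hits_beta, hits_prec = 0, 0
    for seed in range(20):
        data, truth = glm.simulate_optimization_dataset(seed)
        fm = glm.invert(data, glm.default_priors(4, 2))
        mean = fm.posterior.mean
        sd = np.sqrt(fm.posterior.variances)
        hits_beta += np.all(np.abs(mean[:4] - 1.0) <= 3 * sd[:4])
        hits_prec += np.all(np.abs(mean[4:] - [2.0, 1.0]) <= 3 * sd[4:])
    assert hits_beta >= 18
    assert hits_prec >= 18


def test_known_precision_limit_matches_conjugate_oracle():
    """With the noise log-precision pinned by a tight prior, the VL inversion
    must reproduce the exact conjugate posterior and evidence."""
    rng = np.random.default_rng(5)
    n, p = 32, 3
    X = rng.standard_normal((n, p))
    beta = np.array([1.0, -1.0, 0.5])
    noise_var = 0.25
    y = X @ beta + rng.standard_normal(n) * np.sqrt(noise_var)
    data = glm.GLMData(y=y, X=X)
    logprec = -np.log(noise_var)
    priors = glm.GLMPriors(
        beta_mean=np.zeros(p),
        beta_variance=np.full(p, 8.0),
        logprec_mean=np.array([logprec]),
        logprec_variance=np.array([1e-8]),
    )
    fm = glm.invert(data, priors)
    beta_prior = GaussianDensity.from_variances(np.zeros(p), np.full(p, 8.0))
    exact_f = glm.closed_form_evidence(data, beta_prior, np.array([noise_var]))
    # the pinned log-precision factor contributes no extra free energy
    assert abs(fm.free_energy - exact_f) < 0.01
    post_prec = beta_prior.precision + X.T @ X / noise_var
    post_mean = np.linalg.solve(post_prec, X.T @ y / noise_var)
    assert np.allclose(fm.posterior.mean[:p], post_mean, atol=1e-4)
    assert np.allclose(fm.posterior.precision[:p, :p], post_prec, rtol=1e-3)


def test_reduce_on_vl_inversion_matches_conjugate_differences():
    """Evidence differences between switch priors computed by BMR on the
    pinned-precision VL inversion match the conjugate closed form."""
    rng = np.random.default_rng(9)
    n, p = 24, 4
    X = rng.standard_normal((n, p))
    y = X @ np.array([1.0, 1.0, 0.0, 0.0]) + rng.standard_normal(n) * 0.5
    data = glm.GLMData(y=y, X=X)
    noise_var = 0.25
    priors = glm.GLMPriors(
        beta_mean=np.zeros(p),
        beta_variance=np.full(p, 8.0),
        logprec_mean=np.array([-np.log(noise_var)]),
        logprec_variance=np.array([1e-6]),
    )
    fm = glm.invert(data, priors)
    for keep in ([0, 1], [0, 1, 2]):
        var = np.array([8.0 if j in keep else 0.0 for j in range(p)])
        reduced_beta = GaussianDensity.from_variances(np.zeros(p), var)
        # embed into the joint (beta, logprec) prior
        joint_var = np.concatenate([var, [1e-6]])
        joint = GaussianDensity.from_variances(
            np.concatenate([np.zeros(p), priors.logprec_mean]),
            joint_var,
            fm.prior.labels,
        )
        res = core.reduce(fm, joint)
        Xk = X[:, keep]
        sub = glm.GLMData(y=y, X=Xk)
        pk = GaussianDensity.from_variances(
            np.zeros(len(keep)), np.full(len(keep), 8.0)
        )
        exact_diff = glm.closed_form_evidence(
            sub, pk, np.array([noise_var])
        ) - glm.closed_form_evidence(
            data,
            GaussianDensity.from_variances(np.zeros(p), np.full(p, 8.0)),
            np.array([noise_var]),
        )
        assert abs(res.delta_f - exact_diff) < 1e-3


def test_invert_validates_inputs():
    data, _ = glm.simulate_optimization_dataset(0)
    with pytest.raises(ValueError):
        glm.invert(data, glm.default_priors(5, 2))
    with pytest.raises(ValueError):
        glm.invert(data, glm.default_priors(4, 1))
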