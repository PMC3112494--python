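"""Shared helpers: small random Gaussian models and conjugate GLM oracles."""

from __future__ import annotations

import numpy as np
import pytest

from bmr.core import FullModel
from bmr.gaussian import GaussianDensity


def random_spd(rng: np.random.Generator, d: int, scale: float = 1.0) -> np.ndarray:
    """Random symmetric positive-definite matrix."""
    a = rng.standard_normal((d, d))
    return scale * (a @ a.T + d * np.eye(d))


def random_full_model(
    rng: np.random.Generator, d: int, diagonal_prior: bool = False
) -> FullModel:
    """A consistent (prior, posterior) pair from a conjugate construction:
    posterior precision = prior precision + likelihood precision, posterior
    mean pulled toward a random data mode.  Guarantees the posterior is at
    least as precise as the prior, as any exact Bayesian update would be."""
    if diagonal_prior:
        prior_prec = np.diag(1.0 / rng.uniform(0.5, 4.0, size=d))
    else:
        prior_prec = random_spd(rng, d, 0.5)
    like_prec = random_spd(rng, d, 1.0)
    prior_mean = rng.standard_normal(d)
    data_mode = rng.standard_normal(d)
    post_prec = prior_prec + like_prec
    post_mean = np.linalg.solve(
        post_prec, prior_prec @ prior_mean + like_prec @ data_mode
    )
    return FullModel(
        prior=GaussianDensity(prior_mean, prior_prec),
        posterior=GaussianDensity(post_mean, post_prec),
        free_energy=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
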