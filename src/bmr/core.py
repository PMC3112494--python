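"""Closed-form Bayesian model reduction under the Laplace assumption.

Given a single inversion of a *full* model -- Gaussian prior N(eta_F, Pi_F^-1),
Gaussian posterior N(mu_F, P_F^-1) and a free-energy approximation F_F to the
log-evidence -- the evidence and posterior of any *reduced* model (same
likelihood, different prior) follow analytically:

    P_i  = P_F + Pi_i - Pi_F
    mu_i = P_i^-1 (P_F mu_F + Pi_i eta_i - Pi_F eta_F)
    F_i  = F_F + 1/2 ln[ det(Pi_i) det(P_F) / (det(P_i) det(Pi_F)) ]
              - 1/2 [ mu_F' P_F mu_F + eta_i' Pi_i eta_i
                      - eta_F' Pi_F eta_F - mu_i' P_i mu_i ]

Parameters removed from the model (prior variance collapsed to zero) are
handled exactly by block partitioning: their contribution is the
Savage-Dickey density ratio of the posterior to the prior marginal at the
clamped value, and they drop out of the determinant terms entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .gaussian import DegenerateMarginalError, GaussianDensity, _logdet_pd

__all__ = [
    "FullModel",
    "ReducedResult",
    "SupportError",
    "InvalidReductionError",
    "reduce",
    "clamp",
    "model_posterior",
    "pool_subjects",
]

_PD_RTOL = 1e-8


class SupportError(ValueError):
    """Reduced prior places mass where the full prior has none."""


class InvalidReductionError(ValueError):
    """The implied reduced posterior precision is not positive definite."""


@dataclass(frozen=True)
class FullModel:
    """A full-model inversion: Gaussian prior, Gaussian posterior, free energy.

    ``free_energy`` defaults to 0 when the inversion scheme does not report
    one; all model comparisons then rest on ``delta_f`` alone, which is
    unaffected by this constant.
    """

    prior: GaussianDensity
    posterior: GaussianDensity
    free_energy: float = 0.0
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.prior.dim != self.posterior.dim:
            raise ValueError(
                f"prior dimension {self.prior.dim} != posterior dimension "
                f"{self.posterior.dim}"
            )
        _check_labels(self.prior, self.posterior, "prior", "posterior")
        if not np.array_equal(self.prior.point_mass, self.posterior.point_mass):
            raise ValueError(
                "prior and posterior must agree on point-mass coordinates"
            )
        pm = self.prior.point_mass
        if pm.any() and not np.allclose(
            self.prior.mean[pm], self.posterior.mean[pm]
        ):
            raise ValueError("point-mass coordinates must have equal means")
        free = ~pm
        if free.any():
            block = self.posterior.precision[np.ix_(free, free)]
            eig = np.linalg.eigvalsh(block)
            if eig[0] <= _PD_RTOL * max(eig[-1], 1.0):
                raise ValueError("posterior precision must be positive definite")

    @property
    def dim(self) -> int:
        return self.prior.dim


@dataclass(frozen=True)
class ReducedResult:
    """Outcome of a model reduction.

    ``delta_f = free_energy - F_F`` is the log Bayes factor of the reduced
    model against the full model.  ``clamped_indices`` lists the coordinates
    whose prior was collapsed to a point mass, with the clamp values.
    """

    free_energy: float
    delta_f: float
    posterior: GaussianDensity
    reduced_prior: GaussianDensity
    clamped_indices: tuple[tuple[int, float], ...] = ()


def _check_labels(a: GaussianDensity, b: GaussianDensity, na: str, nb: str) -> None:
    if a.labels is not None and b.labels is not None and a.labels != b.labels:
        raise ValueError(
            f"label mismatch between {na} and {nb}: {a.labels} vs {b.labels}; "
            "densities are joined by label and are never silently reordered"
        )


def reduce(full: FullModel, reduced_prior: GaussianDensity) -> ReducedResult:
    """Evidence and posterior of the model whose prior is ``reduced_prior``.

    The reduced prior may collapse coordinates to point masses (zero
    variance); these are handled by the exact Savage-Dickey partition rather
    than by a finite precision.

    Raises
    ------
    ValueError
        On dimension or label mismatch.
    SupportError
        If a direction with zero full-prior variance has non-zero reduced
        variance or a different mean.
    InvalidReductionError
        If ``P_F + Pi_i - Pi_F`` is not positive definite.
    """
    prior, post = full.prior, full.posterior
    if reduced_prior.dim != prior.dim:
        raise ValueError(
            f"reduced prior dimension {reduced_prior.dim} != model dimension "
            f"{prior.dim}"
        )
    _check_labels(prior, reduced_prior, "full prior", "reduced prior")

    carried = prior.point_mass
    if carried.any():
        bad = carried & ~reduced_prior.point_mass
        if bad.any():
            raise SupportError(
                f"coordinates {np.where(bad)[0].tolist()} have zero full-prior "
                "variance but non-zero reduced-prior variance"
            )
        if not np.allclose(prior.mean[carried], reduced_prior.mean[carried]):
            raise SupportError(
                "point-mass coordinates of the full prior must keep their mean "
                "in the reduced prior"
            )

    newly_clamped = reduced_prior.point_mass & ~carried
    c_idx = np.where(newly_clamped)[0]
    clamp_values = reduced_prior.mean[c_idx]

    delta_f = 0.0
    # Savage-Dickey contribution of the clamped block: ratio of posterior to
    # prior marginal density at the clamp values.
    if c_idx.size:
        delta_f += post.marginal_logpdf(c_idx, clamp_values)
        delta_f -= prior.marginal_logpdf(c_idx, clamp_values)
        post_c = post.condition(c_idx, clamp_values)
        prior_c = prior.condition(c_idx, clamp_values)
    else:
        post_c, prior_c = post, prior

    # remaining free coordinates, in the conditioned frame
    keep = np.where(~newly_clamped)[0]
    free_keep = ~reduced_prior.point_mass[keep] & ~carried[keep]
    r_local = np.where(free_keep)[0]
    r_global = keep[r_local]

    mu_i_r = np.empty(0)
    p_i = np.empty((0, 0))
    if r_local.size:
        pf = post_c.precision[np.ix_(r_local, r_local)]
        mu_f = post_c.mean[r_local]
        pi_f = prior_c.precision[np.ix_(r_local, r_local)]
        eta_f = prior_c.mean[r_local]
        pi_i = reduced_prior.precision[np.ix_(r_global, r_global)]
        eta_i = reduced_prior.mean[r_global]

        p_i = pf + pi_i - pi_f
        eig, vec = np.linalg.eigh(p_i)
        if eig[0] <= _PD_RTOL * max(eig[-1], 1.0):
            worst = vec[:, 0]
            k = int(np.argmax(np.abs(worst)))
            name = (
                reduced_prior.labels[r_global[k]]
                if reduced_prior.labels is not None
                else f"parameter {r_global[k]}"
            )
            raise InvalidReductionError(
                "invalid reduction: reduced posterior precision has a "
                f"non-positive eigenvalue ({eig[0]:.3e}) along a direction "
                f"dominated by {name}"
            )
        mu_i_r = np.linalg.solve(p_i, pf @ mu_f + pi_i @ eta_i - pi_f @ eta_f)

        delta_f += 0.5 * (
            _logdet_pd(pi_i) + _logdet_pd(pf) - _logdet_pd(p_i) - _logdet_pd(pi_f)
        )
        delta_f -= 0.5 * (
            float(mu_f @ pf @ mu_f)
            + float(eta_i @ pi_i @ eta_i)
            - float(eta_f @ pi_f @ eta_f)
            - float(mu_i_r @ p_i @ mu_i_r)
        )

    # assemble the reduced posterior over all coordinates
    d = prior.dim
    mean = np.empty(d)
    prec = np.zeros((d, d))
    pm = reduced_prior.point_mass.copy()
    mean[c_idx] = clamp_values
    mean[carried] = prior.mean[carried]
    if r_global.size:
        mean[r_global] = mu_i_r
        prec[np.ix_(r_global, r_global)] = p_i
    posterior = GaussianDensity(mean, prec, prior.labels, pm)

    f_i = full.free_energy + delta_f
    return ReducedResult(
        free_energy=f_i,
        delta_f=delta_f,
        posterior=posterior,
        reduced_prior=reduced_prior,
        clamped_indices=tuple(
            (int(i), float(v)) for i, v in zip(c_idx, clamp_values)
        ),
    )


def clamp(
    full: FullModel, indices: Sequence[int], values: Sequence[float]
) -> ReducedResult:
    """Fix parameters at given values: the Savage-Dickey density ratio.

    The reduced prior is the full prior with the indexed coordinates collapsed
    to point masses at ``values`` (the limit of prior variance -> 0); the
    remaining coordinates keep the full prior, conditioned on the clamp.  The
    log Bayes factor is the posterior-to-prior marginal log-density ratio at
    the clamp values, and the reduced posterior over the remaining parameters
    is the full-posterior conditional.
    """
    idx = np.atleast_1d(np.asarray(indices, dtype=int))
    vals = np.atleast_1d(np.asarray(values, dtype=float))
    if idx.size != np.unique(idx).size:
        raise ValueError("clamp indices must be distinct")
    if idx.size != vals.size:
        raise ValueError("indices and values must have equal length")
    if idx.size and (idx.min() < 0 or idx.max() >= full.dim):
        raise ValueError("clamp index out of range")
    prior = full.prior
    if prior.point_mass[idx].any():
        raise DegenerateMarginalError(
            "cannot clamp a coordinate whose full prior is already a point mass"
        )

    d = prior.dim
    keep = np.setdiff1d(np.arange(d), idx)
    cond = prior.condition(idx, vals)
    mean = np.empty(d)
    prec = np.zeros((d, d))
    pm = prior.point_mass.copy()
    pm[idx] = True
    mean[idx] = vals
    mean[keep] = cond.mean
    prec[np.ix_(keep, keep)] = cond.precision
    reduced_prior = GaussianDensity(mean, prec, prior.labels, pm)
    return reduce(full, reduced_prior)


def model_posterior(free_energies: np.ndarray) -> np.ndarray:
    """Posterior model probabilities under flat model priors.

    The softmax of the log-evidences, computed with the max subtracted for
    numerical stability; invariant to adding a constant to every entry.
    """
    f = np.atleast_1d(np.asarray(free_energies, dtype=float))
    if f.size == 0:
        raise ValueError("need at least one free energy")
    if not np.all(np.isfinite(f)):
        raise ValueError("free energies must be finite")
    w = np.exp(f - f.max())
    return w / w.sum()


def pool_subjects(per_subject_delta_f: np.ndarray) -> np.ndarray:
    """Fixed-effects pooling: sum log-evidences over subjects.

    ``per_subject_delta_f`` has one row per model and one column per subject;
    returns the row sums.  The pooled model posterior is
    ``model_posterior(pool_subjects(...))``.
    """
    mat = np.atleast_2d(np.asarray(per_subject_delta_f, dtype=float))
    if not np.all(np.isfinite(mat)):
        raise ValueError("per-subject log-evidences must be finite")
    return mat.sum(axis=1)
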