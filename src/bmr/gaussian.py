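"""Multivariate Gaussian densities parameterized by mean and precision.

The density type used throughout the package stores a mean vector and a
precision (inverse covariance) matrix.  Point-mass coordinates -- directions
whose variance is exactly zero, e.g. parameters removed from a model by an
infinitely precise shrinkage prior -- are represented explicitly by a boolean
mask rather than by a large-but-finite precision, so that downstream linear
algebra can partition them out exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GaussianDensity", "DegenerateMarginalError"]

#: relative tolerance for symmetry / eigenvalue checks
_EIG_RTOL = 1e-8


class DegenerateMarginalError(ValueError):
    """Raised when a marginal or conditional requires inverting a singular block."""


def _symmetrize(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m + m.T)


def _logdet_pd(m: np.ndarray) -> float:
    """Log-determinant of a symmetric positive-definite matrix via Cholesky."""
    if m.size == 0:
        return 0.0
    try:
        chol = np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise DegenerateMarginalError(
            "matrix is not positive definite; cannot take log-determinant"
        ) from exc
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


@dataclass(frozen=True)
class GaussianDensity:
    """A d-dimensional Gaussian N(mean, precision^-1), allowing point masses.

    Parameters
    ----------
    mean
        Length-d mean vector.
    precision
        d x d symmetric positive-semidefinite precision matrix.  Rows and
        columns of point-mass coordinates are zero (the precision there is
        conceptually infinite and handled by partitioning).
    labels
        Optional parameter names, used as join keys between densities.
    point_mass
        Boolean mask of coordinates with zero variance.
    """

    mean: np.ndarray
    precision: np.ndarray
    labels: tuple[str, ...] | None = None
    point_mass: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        prec = np.asarray(self.precision, dtype=float)
        if prec.ndim != 2 or prec.shape[0] != prec.shape[1]:
            raise ValueError("precision must be a square matrix")
        if mean.shape[0] != prec.shape[0]:
            raise ValueError(
                f"dimension mismatch: mean has length {mean.shape[0]}, "
                f"precision is {prec.shape[0]}x{prec.shape[1]}"
            )
        scale = np.abs(prec).max() if prec.size else 0.0
        if scale > 0 and np.abs(prec - prec.T).max() > 1e-6 * scale:
            raise ValueError("precision matrix is not symmetric")
        prec = _symmetrize(prec)
        pm = self.point_mass
        if pm is None:
            pm = np.zeros(mean.shape[0], dtype=bool)
        else:
            pm = np.asarray(pm, dtype=bool)
            if pm.shape[0] != mean.shape[0]:
                raise ValueError("point_mass mask has wrong length")
        # point-mass rows/columns of the precision must be zero
        if pm.any():
            prec = prec.copy()
            prec[pm, :] = 0.0
            prec[:, pm] = 0.0
        free = ~pm
        if free.any():
            block = prec[np.ix_(free, free)]
            eig = np.linalg.eigvalsh(block)
            if eig.size and eig[0] < -_EIG_RTOL * max(eig[-1], 1.0):
                raise ValueError(
                    f"precision has a negative eigenvalue ({eig[0]:.3e})"
                )
        labels = self.labels
        if labels is not None:
            labels = tuple(labels)
            if len(labels) != mean.shape[0]:
                raise ValueError("labels length does not match dimension")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "precision", prec)
        object.__setattr__(self, "point_mass", pm)
        object.__setattr__(self, "labels", labels)

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #
    @classmethod
    def from_covariance(
        cls,
        mean: np.ndarray,
        covariance: np.ndarray,
        labels: tuple[str, ...] | None = None,
    ) -> "GaussianDensity":
        """Build from a covariance matrix.

        Zero-variance coordinates (diagonal entry, and hence the whole
        row/column, below tolerance) are flagged as point masses; any other
        singular eigendirection raises, since it cannot be attributed to a
        single coordinate.
        """
        cov = _symmetrize(np.asarray(covariance, dtype=float))
        d = cov.shape[0]
        scale = np.abs(cov).max() if cov.size else 1.0
        tol = _EIG_RTOL * max(scale, 1.0)
        pm = np.zeros(d, dtype=bool)
        for k in range(d):
            if abs(cov[k, k]) <= tol:
                if np.abs(cov[k, :]).max(initial=0.0) > tol:
                    raise ValueError(
                        f"coordinate {k} has zero variance but non-zero covariance"
                    )
                pm[k] = True
        free = ~pm
        prec = np.zeros_like(cov)
        if free.any():
            block = cov[np.ix_(free, free)]
            eig = np.linalg.eigvalsh(block)
            if eig[0] <= tol:
                raise ValueError(
                    "covariance has a singular eigendirection that is not "
                    "axis-aligned; cannot convert to precision"
                )
            prec[np.ix_(free, free)] = np.linalg.inv(block)
        return cls(np.asarray(mean, dtype=float), prec, labels, pm)

    @classmethod
    def from_variances(
        cls,
        mean: np.ndarray,
        variances: np.ndarray,
        labels: tuple[str, ...] | None = None,
    ) -> "GaussianDensity":
        """Diagonal Gaussian from per-coordinate variances (zeros allowed)."""
        var = np.atleast_1d(np.asarray(variances, dtype=float))
        if (var < 0).any():
            raise ValueError("variances must be non-negative")
        pm = var == 0.0
        prec = np.zeros((var.size, var.size))
        idx = np.where(~pm)[0]
        prec[idx, idx] = 1.0 / var[idx]
        return cls(np.asarray(mean, dtype=float), prec, labels, pm)

    # ------------------------------------------------------------------ #
    # basic properties
    # ------------------------------------------------------------------ #
    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        """Covariance matrix; point-mass rows/columns are zero."""
        free = ~self.point_mass
        cov = np.zeros_like(self.precision)
        if free.any():
            block = self.precision[np.ix_(free, free)]
            eig = np.linalg.eigvalsh(block)
            if eig[0] <= _EIG_RTOL * max(eig[-1], 1.0):
                raise DegenerateMarginalError(
                    "precision is singular; covariance does not exist"
                )
            cov[np.ix_(free, free)] = np.linalg.inv(block)
        return cov

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.covariance).copy()

    def is_proper(self) -> bool:
        """True if the density has finite, invertible precision (no point mass
        and no zero-precision direction)."""
        if self.point_mass.any():
            return False
        eig = np.linalg.eigvalsh(self.precision)
        return bool(eig.size == 0 or eig[0] > _EIG_RTOL * max(eig[-1], 1.0))

    # ------------------------------------------------------------------ #
    # marginals, conditionals and densities
    # ------------------------------------------------------------------ #
    def marginal(self, indices: np.ndarray) -> "GaussianDensity":
        """Marginal density over the given coordinates (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        cov = self.covariance
        sub_labels = (
            tuple(self.labels[i] for i in idx) if self.labels is not None else None
        )
        return GaussianDensity.from_covariance(
            self.mean[idx], cov[np.ix_(idx, idx)], sub_labels
        )

    def condition(self, indices: np.ndarray, values: np.ndarray) -> "GaussianDensity":
        """Conditional density of the remaining coordinates given
        ``x[indices] = values``.

        Uses the precision-matrix identities: the conditional precision of the
        free block is its sub-block of the joint precision, and the
        conditional mean shifts by ``-P_rr^{-1} P_rc (v - mean_c)``.
        """
        idx = np.asarray(indices, dtype=int)
        values = np.atleast_1d(np.asarray(values, dtype=float))
        if self.point_mass[idx].any():
            raise DegenerateMarginalError(
                "cannot condition on a point-mass coordinate"
            )
        keep = np.setdiff1d(np.arange(self.dim), idx)
        p_rr = self.precision[np.ix_(keep, keep)]
        p_rc = self.precision[np.ix_(keep, idx)]
        shift = values - self.mean[idx]
        free_keep = ~self.point_mass[keep]
        mean_r = self.mean[keep].copy()
        if free_keep.any():
            block = p_rr[np.ix_(free_keep, free_keep)]
            rhs = p_rc[free_keep, :] @ shift
            try:
                mean_r[free_keep] -= np.linalg.solve(block, rhs)
            except np.linalg.LinAlgError as exc:
                raise DegenerateMarginalError(
                    "conditional precision block is singular"
                ) from exc
        sub_labels = (
            tuple(self.labels[i] for i in keep) if self.labels is not None else None
        )
        return GaussianDensity(mean_r, p_rr, sub_labels, self.point_mass[keep])

    def marginal_logpdf(self, indices: np.ndarray, values: np.ndarray) -> float:
        """Log density of the marginal over ``indices`` evaluated at ``values``."""
        idx = np.asarray(indices, dtype=int)
        values = np.atleast_1d(np.asarray(values, dtype=float))
        if self.point_mass[idx].any():
            raise DegenerateMarginalError(
                "marginal over a point-mass coordinate has no density"
            )
        cov = self.covariance[np.ix_(idx, idx)]
        diff = values - self.mean[idx]
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise DegenerateMarginalError("marginal covariance is singular") from exc
        z = np.linalg.solve(chol, diff)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        return -0.5 * (idx.size * np.log(2.0 * np.pi) + logdet + float(z @ z))

    # ------------------------------------------------------------------ #
    # helpers
    # ------------------------------------------------------------------ #
    def logdet_precision(self) -> float:
        """Log-determinant of the precision on the free (non-point-mass) block."""
        free = ~self.point_mass
        return _logdet_pd(self.precision[np.ix_(free, free)])

    def with_labels(self, labels: tuple[str, ...]) -> "GaussianDensity":
        return GaussianDensity(self.mean, self.precision, tuple(labels), self.point_mass)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, GaussianDensity):
            return NotImplemented
        return (
            np.array_equal(self.mean, other.mean)
            and np.array_equal(self.precision, other.precision)
            and np.array_equal(self.point_mass, other.point_mass)
            and self.labels == other.labels
        )
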