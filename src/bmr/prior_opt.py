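"""Continuous model spaces: optimize prior hyperparameters by evidence ascent.

A ``PriorFamily`` maps a hyperparameter vector lambda to a Gaussian prior
(eta(lambda), Pi(lambda)); the reduced free energy F(lambda) of each such
prior follows in closed form from a single full-model inversion.  Maximizing
F(lambda) over prior means and variances is empirical Bayes; when the
hyperparameters are per-parameter prior variances, evidence ascent collapses
the variances of irrelevant parameters to zero -- automatic relevance
determination.

The ascent is a quasi-Newton scheme on a transformed scale (variances are
optimized as log-variances) with finite-difference derivatives and
backtracking step halving, run from the supplied start plus a small number of
jittered restarts to guard against local maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from . import core
from .gaussian import GaussianDensity

__all__ = [
    "PriorFamily",
    "OptimizationResult",
    "StuckError",
    "free_energy_of",
    "optimize",
    "profile",
    "shared_mean_variance_family",
    "per_param_variance_family",
]

FD_STEP = 1e-3          # finite-difference step on the transformed scale
F_TOL = 1e-4            # convergence: accepted step improves F by less than this
GRAD_TOL = 1e-2         # ... and the interior gradient is this flat
MAX_STEP_NORM = 4.0     # trust region on the transformed scale
MAX_ITER = 128
MAX_HALVINGS = 16
N_JITTER = 4            # restarts beyond the supplied start


class StuckError(RuntimeError):
    """Every point in the optimizer's neighborhood is infeasible."""


@dataclass(frozen=True)
class PriorFamily:
    """A differentiable map from hyperparameters to reduced priors.

    ``transforms[k]`` is ``"identity"`` (means) or ``"log"`` (variances); the
    optimizer works on the transformed scale, so log-variances are
    unconstrained apart from the box ``bounds`` (given on the natural scale).
    """

    param_fn: Callable[[np.ndarray], GaussianDensity]
    bounds: tuple[tuple[float, float], ...]
    transforms: tuple[str, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.transforms):
            raise ValueError("bounds and transforms must have equal length")
        for t in self.transforms:
            if t not in ("identity", "log"):
                raise ValueError(f"unknown transform {t!r}")
        for (lo, hi), t in zip(self.bounds, self.transforms):
            if not lo < hi:
                raise ValueError("each bound must satisfy lo < hi")
            if t == "log" and lo <= 0:
                raise ValueError("log-transformed hyperparameters need lo > 0")

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def in_bounds(self, lam: np.ndarray) -> bool:
        lam = np.asarray(lam, dtype=float)
        return all(lo <= v <= hi for v, (lo, hi) in zip(lam, self.bounds))

    def to_transformed(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        return np.array(
            [np.log(v) if t == "log" else v for v, t in zip(lam, self.transforms)]
        )

    def from_transformed(self, z: np.ndarray) -> np.ndarray:
        return np.array(
            [np.exp(v) if t == "log" else v for v, t in zip(z, self.transforms)]
        )

    def transformed_bounds(self) -> np.ndarray:
        return np.array(
            [
                (np.log(lo), np.log(hi)) if t == "log" else (lo, hi)
                for (lo, hi), t in zip(self.bounds, self.transforms)
            ]
        )


@dataclass(frozen=True)
class OptimizationResult:
    """Optimized hyperparameters with the corresponding reduction.

    Unpacks as ``lam_star, reduced = optimize(...)`` for convenience.
    """

    lam: np.ndarray
    reduced: core.ReducedResult
    free_energy: float
    trajectory: list[dict[str, Any]] = field(default_factory=list)
    at_lower_bound: np.ndarray = None  # type: ignore[assignment]
    converged: bool = True

    def __iter__(self):
        return iter((self.lam, self.reduced))


def free_energy_of(
    full: core.FullModel, family: PriorFamily, lam: Sequence[float]
) -> float:
    """F(lambda): reduced free energy of the prior the family assigns to
    ``lam``; ``-inf`` when the reduction is invalid (infeasible prior)."""
    lam = np.asarray(lam, dtype=float)
    if lam.shape[0] != family.dim:
        raise ValueError("hyperparameter vector has wrong length")
    # snap round-off-level violations (log/exp round trips) onto the box
    b = np.asarray(family.bounds, dtype=float)
    tol = 1e-9 * np.maximum(np.abs(b[:, 0]), np.abs(b[:, 1]))
    if ((lam < b[:, 0] - tol) | (lam > b[:, 1] + tol)).any():
        raise ValueError(f"lambda {lam.tolist()} outside the family bounds")
    lam = np.clip(lam, b[:, 0], b[:, 1])
    try:
        return core.reduce(full, family.param_fn(lam)).free_energy
    except (core.InvalidReductionError, core.SupportError):
        return -np.inf


def _fd_derivatives(
    fun: Callable[[np.ndarray], float],
    z: np.ndarray,
    f0: float,
    lo: np.ndarray,
    hi: np.ndarray,
    full_hessian: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient and (full or diagonal) Hessian, clipping
    evaluation points to the transformed box."""
    h = FD_STEP
    d = z.size
    grad = np.zeros(d)
    fp = np.zeros(d)
    fm = np.zeros(d)

    def ev(p: np.ndarray) -> float:
        return fun(np.clip(p, lo, hi))

    any_finite = False
    for k in range(d):
        zp, zm = z.copy(), z.copy()
        zp[k] += h
        zm[k] -= h
        fp[k], fm[k] = ev(zp), ev(zm)
        if np.isfinite(fp[k]) or np.isfinite(fm[k]):
            any_finite = True
        if np.isfinite(fp[k]) and np.isfinite(fm[k]):
            grad[k] = (fp[k] - fm[k]) / (2 * h)
        elif np.isfinite(fp[k]):
            grad[k] = (fp[k] - f0) / h
        elif np.isfinite(fm[k]):
            grad[k] = (f0 - fm[k]) / h
    if not any_finite:
        raise StuckError(
            "all finite-difference neighbors are infeasible (invalid reductions)"
        )
    hess = np.zeros((d, d))
    diag = np.where(
        np.isfinite(fp) & np.isfinite(fm), (fp - 2 * f0 + fm) / h**2, -1.0
    )
    np.fill_diagonal(hess, diag)
    if full_hessian and d > 1:
        for i in range(d):
            for j in range(i + 1, d):
                zpp = z.copy(); zpp[[i, j]] += h
                zmm = z.copy(); zmm[[i, j]] -= h
                fpp, fmm = ev(zpp), ev(zmm)
                if np.isfinite(fpp) and np.isfinite(fmm):
                    hij = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                        2 * h**2
                    )
                    hess[i, j] = hess[j, i] = hij
    return grad, hess


def _ascend(
    fun: Callable[[np.ndarray], float],
    z0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    trajectory: list[dict[str, Any]],
) -> tuple[np.ndarray, float, bool]:
    """Quasi-Newton ascent with backtracking, in the transformed box."""
    z = np.clip(z0, lo, hi)
    f = fun(z)
    if not np.isfinite(f):
        return z, f, False
    full_hess = z.size <= 3
    converged = False
    for _ in range(MAX_ITER):
        grad, hess = _fd_derivatives(fun, z, f, lo, hi, full_hess)
        # Newton direction on -hess, regularized to be positive definite
        neg_h = -hess
        eig = np.linalg.eigvalsh(neg_h) if z.size > 1 else neg_h.ravel()
        ridge = max(0.0, 1e-6 - float(np.min(eig)))
        try:
            step = np.linalg.solve(neg_h + ridge * np.eye(z.size), grad)
        except np.linalg.LinAlgError:
            step = grad
        if not np.all(np.isfinite(step)) or float(step @ grad) <= 0:
            step = grad
        # trust region: a near-singular regularized Hessian can propose steps
        # too long for backtracking to rescue
        norm = float(np.linalg.norm(step))
        if norm > MAX_STEP_NORM:
            step = step * (MAX_STEP_NORM / norm)

        def backtrack(direction: np.ndarray):
            s = direction
            for _ in range(MAX_HALVINGS):
                z_try = np.clip(z + s, lo, hi)
                f_try = fun(z_try)
                if np.isfinite(f_try) and f_try > f:
                    return z_try, f_try
                s = 0.5 * s
            return None

        hit = backtrack(step)
        if hit is None and not np.allclose(step, grad):
            gnorm = float(np.linalg.norm(grad))
            if gnorm > 0:
                hit = backtrack(grad / gnorm)
        if hit is None:
            converged = True
            break
        z_new, f_new = hit
        trajectory.append({"z": z_new.tolist(), "f": float(f_new)})
        # a small step alone is not convergence on a curved ridge; require
        # the (interior-coordinate) gradient to be flat as well
        interior = (z_new > lo + FD_STEP) & (z_new < hi - FD_STEP)
        flat = not interior.any() or np.abs(grad[interior]).max() < GRAD_TOL
        if f_new - f < F_TOL and flat:
            z, f = z_new, f_new
            converged = True
            break
        z, f = z_new, f_new
    return z, f, converged


def optimize(
    full: core.FullModel,
    family: PriorFamily,
    lam0: Sequence[float],
    seed: int = 0,
) -> OptimizationResult:
    """Maximize F(lambda) over the family from ``lam0`` plus jittered restarts.

    Guarantees ``F(lam*) >= F(lam0)`` (the start is always a candidate).
    Hyperparameters whose transformed value finishes at the lower bound are
    flagged in ``at_lower_bound`` -- for log-variance hyperparameters this is
    the collapse-to-zero (parameter removal) signature.
    """
    lam0 = np.asarray(lam0, dtype=float)
    f0 = free_energy_of(full, family, lam0)
    if not np.isfinite(f0):
        raise ValueError("F(lam0) must be finite")
    tb = family.transformed_bounds()
    lo, hi = tb[:, 0], tb[:, 1]
    z0 = family.to_transformed(lam0)

    def fun(z: np.ndarray) -> float:
        return free_energy_of(full, family, family.from_transformed(z))

    rng = np.random.default_rng(seed)
    starts = [z0]
    span = np.minimum(hi - lo, 8.0)
    for _ in range(N_JITTER):
        starts.append(np.clip(z0 + rng.normal(0, 0.25 * span), lo, hi))

    best_z, best_f, best_traj, best_conv = z0, f0, [], True
    for z_start in starts:
        traj: list[dict[str, Any]] = []
        z, f, conv = _ascend(fun, z_start, lo, hi, traj)
        if f > best_f:
            best_z, best_f, best_traj, best_conv = z, f, traj, conv
    lam_star = family.from_transformed(best_z)
    reduced = core.reduce(full, family.param_fn(lam_star))
    at_lb = np.isclose(best_z, lo, atol=1e-9)
    return OptimizationResult(
        lam=lam_star,
        reduced=reduced,
        free_energy=best_f,
        trajectory=best_traj,
        at_lower_bound=at_lb,
        converged=best_conv,
    )


def profile(
    full: core.FullModel, family: PriorFamily, grid: Sequence[Sequence[float]]
) -> pd.DataFrame:
    """Evaluate F(lambda) over a grid of hyperparameter vectors.

    Returns a DataFrame with one column per hyperparameter (``lam_0`` ...)
    and a ``free_energy`` column, in grid order.
    """
    grid = [np.atleast_1d(np.asarray(g, dtype=float)) for g in grid]
    if not grid:
        raise ValueError("grid must be non-empty")
    rows = []
    for lam in grid:
        rows.append(
            {f"lam_{k}": float(v) for k, v in enumerate(lam)}
            | {"free_energy": free_energy_of(full, family, lam)}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# declarative families
# --------------------------------------------------------------------- #
def shared_mean_variance_family(
    base_prior: GaussianDensity,
    indices: Sequence[int],
    mean_bounds: tuple[float, float] = (-16.0, 16.0),
    variance_bounds: tuple[float, float] = (1e-6, 64.0),
) -> PriorFamily:
    """lambda = (m, v): the indexed parameters share an independent N(m, v)
    prior; everything else keeps the base prior."""
    idx = np.asarray(indices, dtype=int)

    def param_fn(lam: np.ndarray) -> GaussianDensity:
        m, v = float(lam[0]), float(lam[1])
        mean = base_prior.mean.copy()
        prec = base_prior.precision.copy()
        mean[idx] = m
        prec[idx, :] = 0.0
        prec[:, idx] = 0.0
        prec[idx, idx] = 1.0 / v
        return GaussianDensity(mean, prec, base_prior.labels, base_prior.point_mass)

    return PriorFamily(
        param_fn=param_fn,
        bounds=(mean_bounds, variance_bounds),
        transforms=("identity", "log"),
        name="shared_mean_variance",
    )


def per_param_variance_family(
    base_prior: GaussianDensity,
    indices: Sequence[int],
    variance_bounds: tuple[float, float] | None = None,
    gamma: float = 1.0,
) -> PriorFamily:
    """lambda_k = prior variance of the k-th indexed parameter (mean 0).

    The default lower bound ``exp(-16) * gamma`` acts as the exact-zero floor
    for collapse detection; the upper bound is ``exp(4) * gamma``.
    """
    idx = np.asarray(indices, dtype=int)
    if variance_bounds is None:
        variance_bounds = (np.exp(-16.0) * gamma, np.exp(4.0) * gamma)

    def param_fn(lam: np.ndarray) -> GaussianDensity:
        mean = base_prior.mean.copy()
        prec = base_prior.precision.copy()
        mean[idx] = 0.0
        prec[idx, :] = 0.0
        prec[:, idx] = 0.0
        prec[idx, idx] = 1.0 / np.asarray(lam, dtype=float)
        return GaussianDensity(mean, prec, base_prior.labels, base_prior.point_mass)

    return PriorFamily(
        param_fn=param_fn,
        bounds=tuple(variance_bounds for _ in idx),
        transforms=tuple("log" for _ in idx),
        name="per_param_variance",
    )
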