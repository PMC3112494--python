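"""Discrete model spaces defined by binary switch priors, and their search.

A switch vector lambda in {0,1}^K turns each switchable parameter's prior
variance between zero (the parameter is removed by an infinitely precise
shrinkage prior, handled exactly by the Savage-Dickey partition) and a fixed
value gamma.  Constraint groups force sets of switches -- e.g. reciprocal
network connections -- to share one value.  Spaces with up to 2^24 free
switches can be enumerated exhaustively; larger spaces use a greedy search
that repeatedly eliminates the weakest parameters in blocks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from . import core
from .gaussian import GaussianDensity

__all__ = [
    "SwitchSpace",
    "SearchResult",
    "enumerate_switches",
    "prior_for_switches",
    "exhaustive_search",
    "greedy_search",
]

EXHAUSTIVE_CAP = 24


@dataclass(frozen=True)
class SwitchSpace:
    """A discrete model space over binary prior-variance switches.

    Parameters
    ----------
    base_prior
        The full model's prior (defines dimension and the priors of
        non-switchable parameters).
    switchable
        Indices whose prior variance is controlled by a switch.
    gamma
        The fixed prior variance assigned when a switch is on.
    constraints
        Disjoint groups of switchable indices that must share one switch
        value (e.g. pairs of reciprocal connections).
    """

    base_prior: GaussianDensity
    switchable: tuple[int, ...]
    gamma: float
    constraints: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        sw = tuple(int(i) for i in self.switchable)
        if len(set(sw)) != len(sw):
            raise ValueError("switchable indices must be distinct")
        if any(i < 0 or i >= self.base_prior.dim for i in sw):
            raise ValueError("switchable index out of range")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        groups = tuple(tuple(int(i) for i in g) for g in self.constraints)
        seen: set[int] = set()
        for g in groups:
            if not set(g) <= set(sw):
                raise ValueError("constraint groups must be subsets of switchable")
            if seen & set(g):
                raise ValueError("constraint groups must be disjoint")
            seen |= set(g)
        object.__setattr__(self, "switchable", sw)
        object.__setattr__(self, "constraints", groups)

    @property
    def n_params(self) -> int:
        return self.base_prior.dim

    @property
    def groups(self) -> tuple[tuple[int, ...], ...]:
        """Free switch units: constraint groups plus ungrouped singletons,
        ordered by their smallest member."""
        grouped = {i for g in self.constraints for i in g}
        units = list(self.constraints) + [
            (i,) for i in self.switchable if i not in grouped
        ]
        return tuple(sorted(units, key=lambda g: min(g)))

    @property
    def n_free_switches(self) -> int:
        return len(self.groups)

    @property
    def n_models(self) -> int:
        """Size of the model space, 2^(free switches), as an exact integer."""
        return 2 ** self.n_free_switches


@dataclass(frozen=True)
class SearchResult:
    """Scored model space: one switch vector, delta_f and posterior
    probability per model, plus the winning reduction."""

    switch_vectors: tuple[tuple[int, ...], ...]
    delta_f: np.ndarray
    posterior_probs: np.ndarray
    best_index: int
    best_reduced: core.ReducedResult
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def best_switches(self) -> tuple[int, ...]:
        return self.switch_vectors[self.best_index]


def enumerate_switches(space: SwitchSpace) -> list[tuple[int, ...]]:
    """All switch vectors of the space, in deterministic lexicographic order
    over the free switch units, with constraint groups expanded so paired
    indices share a value."""
    k = space.n_free_switches
    if k > EXHAUSTIVE_CAP:
        raise ValueError(
            f"{k} free switches exceed the exhaustive cap of {EXHAUSTIVE_CAP} "
            f"(2^{k} models); use greedy_search instead"
        )
    groups = space.groups
    pos = {i: g for g, unit in enumerate(groups) for i in unit}
    out = []
    for bits in itertools.product((0, 1), repeat=k):
        lam = tuple(bits[pos[i]] for i in space.switchable)
        out.append(lam)
    return out


def prior_for_switches(
    space: SwitchSpace, lam: Sequence[int]
) -> GaussianDensity:
    """Reduced prior for one switch vector: equal to the base prior except on
    switchable indices, where the mean is 0 and the variance is gamma (switch
    on) or exactly zero (switch off, marked for the clamp path)."""
    lam = tuple(int(v) for v in lam)
    if len(lam) != len(space.switchable) or any(v not in (0, 1) for v in lam):
        raise ValueError("switch vector must be 0/1 with one entry per switchable index")
    base = space.base_prior
    d = base.dim
    mean = base.mean.copy()
    prec = base.precision.copy()
    pm = base.point_mass.copy()
    on = [i for i, v in zip(space.switchable, lam) if v == 1]
    off = [i for i, v in zip(space.switchable, lam) if v == 0]
    for i in space.switchable:
        mean[i] = 0.0
        prec[i, :] = 0.0
        prec[:, i] = 0.0
    for i in on:
        prec[i, i] = 1.0 / space.gamma
        pm[i] = False
    for i in off:
        pm[i] = True
    return GaussianDensity(mean, prec, base.labels, pm)


def _tie_break_order(vectors: Sequence[tuple[int, ...]], delta_f: np.ndarray) -> int:
    """Index of the best model: max delta_f, ties broken by fewer ON switches,
    then lexicographically smallest vector."""
    best = None
    best_key = None
    tol = 1e-12 * max(1.0, float(np.abs(delta_f).max()))
    fmax = float(delta_f.max())
    for i, (lam, f) in enumerate(zip(vectors, delta_f)):
        if f < fmax - tol:
            continue
        key = (sum(lam), lam)
        if best is None or key < best_key:
            best, best_key = i, key
    return int(best)


def _fast_scorer_applicable(full: core.FullModel, space: SwitchSpace) -> bool:
    """The partitioned fast path requires a diagonal, proper full prior."""
    prior = full.prior
    if prior.point_mass.any():
        return False
    off = prior.precision - np.diag(np.diag(prior.precision))
    if np.abs(off).max(initial=0.0) > 1e-12 * max(np.abs(prior.precision).max(), 1.0):
        return False
    return bool((np.diag(prior.precision) > 0).all())


class _FastScorer:
    """Cached per-model delta_f for diagonal full priors.

    Shares the posterior covariance factorization and prior log-variances
    across models; each model then costs two small Cholesky factorizations
    (the clamped block's posterior marginal and the free block's reduced
    precision).  Results are identical to :func:`bmr.core.reduce` on the same
    reduced prior, which remains the reference path.
    """

    def __init__(self, full: core.FullModel, space: SwitchSpace) -> None:
        prior, post = full.prior, full.posterior
        self.sw = np.asarray(space.switchable, dtype=int)
        self.gamma = space.gamma
        self.d = prior.dim
        self.mu = post.mean
        self.P = post.precision
        self.sigma = post.covariance
        self.prior_var = np.diag(prior.covariance).copy()
        self.prior_mean = prior.mean
        self.log_prior_var = np.log(self.prior_var)

    def score(self, lam: Sequence[int]) -> float:
        off = self.sw[[v == 0 for v in lam]]
        on = self.sw[[v == 1 for v in lam]]
        keep = np.setdiff1d(np.arange(self.d), off)
        delta_f = 0.0
        # Savage-Dickey term of the clamped block at 0
        if off.size:
            s_cc = self.sigma[np.ix_(off, off)]
            chol = np.linalg.cholesky(s_cc)
            z = np.linalg.solve(chol, self.mu[off])
            delta_f += -0.5 * (
                off.size * np.log(2 * np.pi)
                + 2.0 * np.sum(np.log(np.diag(chol)))
                + float(z @ z)
            )
            pv = self.prior_var[off]
            pz = self.prior_mean[off] / np.sqrt(pv)
            delta_f -= -0.5 * float(
                off.size * np.log(2 * np.pi) + np.sum(np.log(pv)) + pz @ pz
            )
        # conditional posterior over the free block given the clamp at 0
        p_rr = self.P[np.ix_(keep, keep)]
        mu_r = self.mu[keep]
        if off.size:
            mu_r = mu_r + np.linalg.solve(p_rr, self.P[np.ix_(keep, off)] @ self.mu[off])
        # reduced prior on the free block: variance gamma, mean 0 on ON
        # switches; unchanged elsewhere (diagonal prior)
        dprec = np.zeros(self.d)
        dprec[on] = 1.0 / self.gamma - 1.0 / self.prior_var[on]
        w = np.zeros(self.d)  # Pi_i eta_i - Pi_F eta_F
        w[on] = -self.prior_mean[on] / self.prior_var[on]
        p_i = p_rr + np.diag(dprec[keep])
        chol_f = np.linalg.cholesky(p_rr)
        try:
            chol_i = np.linalg.cholesky(p_i)
        except np.linalg.LinAlgError as exc:
            raise core.InvalidReductionError(
                "reduced posterior precision is not positive definite"
            ) from exc
        rhs = p_rr @ mu_r + w[keep]
        mu_i = np.linalg.solve(p_i, rhs)
        ld_pf = 2.0 * np.sum(np.log(np.diag(chol_f)))
        ld_pi = 2.0 * np.sum(np.log(np.diag(chol_i)))
        ld_prior_full = -np.sum(self.log_prior_var[keep])
        ld_prior_red = ld_prior_full + np.sum(self.log_prior_var[on]) - on.size * np.log(
            self.gamma
        )
        eta_f = self.prior_mean[keep]
        eta_quad_f = float(np.sum(eta_f**2 / self.prior_var[keep]))
        eta_quad_i = eta_quad_f - float(
            np.sum(self.prior_mean[on] ** 2 / self.prior_var[on])
        )
        delta_f += 0.5 * (ld_prior_red + ld_pf - ld_pi - ld_prior_full)
        delta_f -= 0.5 * (
            float(mu_r @ p_rr @ mu_r) + eta_quad_i - eta_quad_f - float(mu_i @ p_i @ mu_i)
        )
        return float(delta_f)


def _score_models(
    full: core.FullModel,
    space: SwitchSpace,
    vectors: Sequence[tuple[int, ...]],
) -> tuple[np.ndarray, core.ReducedResult, int]:
    """Delta_f for every vector plus the fully-assembled winner reduction."""
    delta_f = np.empty(len(vectors))
    if _fast_scorer_applicable(full, space):
        scorer = _FastScorer(full, space)
        for i, lam in enumerate(vectors):
            try:
                delta_f[i] = scorer.score(lam)
            except (core.InvalidReductionError, core.SupportError) as exc:
                raise type(exc)(f"{exc} (switch vector {lam})") from exc
    else:
        for i, lam in enumerate(vectors):
            try:
                delta_f[i] = core.reduce(full, prior_for_switches(space, lam)).delta_f
            except (core.InvalidReductionError, core.SupportError) as exc:
                raise type(exc)(f"{exc} (switch vector {lam})") from exc
    best = _tie_break_order(vectors, delta_f)
    best_res = core.reduce(full, prior_for_switches(space, vectors[best]))
    return delta_f, best_res, best


def exhaustive_search(full: core.FullModel, space: SwitchSpace) -> SearchResult:
    """Score every model in the space via the closed-form reduction."""
    vectors = enumerate_switches(space)
    delta_f, best_res, best = _score_models(full, space, vectors)
    if not np.all(np.isfinite(delta_f)):
        raise core.InvalidReductionError("non-finite delta_f in exhaustive search")
    return SearchResult(
        switch_vectors=tuple(vectors),
        delta_f=delta_f,
        posterior_probs=core.model_posterior(delta_f),
        best_index=best,
        best_reduced=best_res,
        meta={"mode": "exhaustive", "gamma": space.gamma},
    )


def greedy_search(
    full: core.FullModel, space: SwitchSpace, block_size: int = 8
) -> SearchResult:
    """Greedy elimination for model spaces too large to enumerate.

    Each sweep ranks the undecided switch units by the evidence lost when
    that unit alone is switched off (on top of units already eliminated),
    takes the ``block_size`` weakest, exhaustively scores all 2^block_size
    submodels over them (everything else on), and permanently eliminates the
    units that are off in the sub-winner.  Sweeps repeat until one removes
    nothing.  The returned result scores every distinct model visited.
    """
    if block_size < 1 or block_size > 16:
        raise ValueError("block_size must be between 1 and 16")
    groups = space.groups
    pos = {i: g for g, unit in enumerate(groups) for i in unit}
    removed: set[int] = set()
    trajectory: list[dict[str, Any]] = []
    visited: dict[tuple[int, ...], float] = {}
    scorer = _FastScorer(full, space) if _fast_scorer_applicable(full, space) else None

    def lam_for(off_units: set[int]) -> tuple[int, ...]:
        return tuple(0 if pos[i] in off_units else 1 for i in space.switchable)

    def score(off_units: set[int]) -> float:
        lam = lam_for(off_units)
        if lam not in visited:
            if scorer is not None:
                visited[lam] = scorer.score(lam)
            else:
                visited[lam] = core.reduce(full, prior_for_switches(space, lam)).delta_f
        return visited[lam]

    score(removed)  # current model
    while True:
        undecided = [g for g in range(len(groups)) if g not in removed]
        if not undecided:
            break
        # rank by the penalty of switching each unit off alone
        penalties = {g: score(removed | {g}) for g in undecided}
        block = sorted(undecided, key=lambda g: (-penalties[g], g))[:block_size]
        fixed_on = [g for g in undecided if g not in block]
        best_sub, best_f = None, -np.inf
        for bits in itertools.product((0, 1), repeat=len(block)):
            off = removed | {g for g, b in zip(block, bits) if b == 0}
            f = score(off)
            n_off = len(off)
            if f > best_f + 1e-12 or (
                abs(f - best_f) <= 1e-12 and best_sub is not None
                and n_off > len(best_sub)
            ):
                best_sub, best_f = off, f
        newly = best_sub - removed
        trajectory.append(
            {
                "block": [list(groups[g]) for g in block],
                "removed": [list(groups[g]) for g in sorted(newly)],
                "delta_f": best_f,
                "fixed_on": len(fixed_on),
            }
        )
        if not newly:
            break
        removed = best_sub

    vectors = list(visited.keys())
    delta_f = np.array([visited[v] for v in vectors])
    best = _tie_break_order(vectors, delta_f)
    return SearchResult(
        switch_vectors=tuple(vectors),
        delta_f=delta_f,
        posterior_probs=core.model_posterior(delta_f),
        best_index=best,
        best_reduced=core.reduce(full, prior_for_switches(space, vectors[best])),
        meta={
            "mode": "greedy",
            "gamma": space.gamma,
            "block_size": block_size,
            "trajectory": trajectory,
        },
    )
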