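"""Simulated maximum likelihood for region-censored weight data.

Thresholding never reveals a respondent's weight vector — only that it lies
in a convex region Omega_j of the simplex.  Under a Dirichlet population
model, respondent j contributes the region probability

    P_j = integral over Omega_j of f(w) dw,

which has no closed form.  Writing the integral against the uniform density
over Omega_j gives ``P_j = (k_j / (n-1)!) * E[f(W)]`` with ``W`` uniform on
Omega_j and ``k_j`` the region's volume fraction of the simplex.  Replacing
the expectation with the average of the density over ``m`` uniform draws
yields the simulated log-likelihood

    SLL = sum_j log( (1/m) sum_i f(w_ij) )   (+ a constant),

where the additive constant collects the ``k_j`` terms.  Because it does
not depend on the parameters, the constant never needs to be computed, and
the fit maximizes the sum above alone.

The ``m`` uniform draws per respondent are generated once and frozen for
the entire optimization (common random numbers), which makes the simulated
likelihood a smooth deterministic function of the parameters.  Densities
are combined in log space with log-sum-exp: when the precision is large and
a region sits far from the mean, the densities span hundreds of orders of
magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .dirichlet import (
    DirichletParams,
    _log_beta,
    _pack,
    _unpack,
    clamp_interior,
    fit_mle,
    moment_estimate,
)
from .polytope import FeasibleWeightSpace

__all__ = [
    "CensoredSample",
    "build_censored_sample",
    "region_probability",
    "simulated_log_likelihood",
    "fit_sml",
    "fit_centroid",
]


@dataclass(frozen=True)
class CensoredSample:
    """Feasible weight spaces plus frozen uniform draws from each.

    ``draws`` has shape ``(N, m, n)``; every ``draws[j]`` lies inside
    ``spaces[j]``.  The draws are the Monte Carlo integration points of the
    simulated likelihood and stay fixed across optimizer iterations.
    """

    spaces: tuple[FeasibleWeightSpace, ...]
    draws: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        N = len(self.spaces)
        if self.draws.ndim != 3 or self.draws.shape[0] != N:
            raise ValueError("draws must have shape (N, m, n)")
        if N and self.draws.shape[2] != self.spaces[0].n:
            raise ValueError("draw dimension does not match the spaces")

    @property
    def N(self) -> int:
        return len(self.spaces)

    @property
    def m(self) -> int:
        return self.draws.shape[1]

    @property
    def n(self) -> int:
        return self.draws.shape[2]

    def centroids(self) -> np.ndarray:
        """Monte Carlo centroid of each region (mean of its draws)."""
        c = self.draws.mean(axis=1)
        return c / c.sum(axis=1, keepdims=True)

    def log_draws(self) -> np.ndarray:
        return np.log(clamp_interior(self.draws))


def build_censored_sample(
    spaces: Sequence[FeasibleWeightSpace], m: int, seed: int
) -> CensoredSample:
    """Draw ``m`` uniform vectors from every space with per-respondent
    child seeds spawned from ``seed``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not spaces:
        raise ValueError("need at least one feasible weight space")
    children = np.random.SeedSequence(seed).spawn(len(spaces))
    draws = np.stack(
        [s.hit_and_run_sample(m, np.random.default_rng(c)) for s, c in zip(spaces, children)]
    )
    return CensoredSample(spaces=tuple(spaces), draws=draws, seed=seed)


def region_probability(
    params: DirichletParams, space: FeasibleWeightSpace, m: int, seed: int
) -> float:
    """Monte Carlo estimate of P = integral of the density over the region.

    Combines the accept-reject volume fraction with the average density
    over uniform draws: ``P = volume_fraction * mean(f) / (n-1)!``, so for
    the flat Dirichlet the result is exactly the volume fraction.  This is
    a diagnostic / validation quantity; the SML fit never evaluates it.
    """
    vol_seed, draw_seed = np.random.SeedSequence(seed).spawn(2)
    k = space.volume_fraction(m, np.random.default_rng(vol_seed))
    draws = space.hit_and_run_sample(m, np.random.default_rng(draw_seed))
    a = params.alpha
    logf = np.log(clamp_interior(draws)) @ (a - 1.0) - _log_beta(a)
    mean_f = math.exp(logsumexp(logf) - math.log(m))
    return k * mean_f / math.factorial(space.n - 1)


def simulated_log_likelihood(
    params: DirichletParams,
    censored: CensoredSample,
    *,
    log_region_constants: np.ndarray | None = None,
) -> float:
    """Simulated log-likelihood of the Dirichlet parameters.

    Computes ``sum_j log((1/m) sum_i f(w_ij))`` over the frozen draws.  The
    parameter-free constant that would complete each ``log P_j`` (the log
    volume fractions) is omitted by default; ``log_region_constants`` adds
    a per-respondent constant, which shifts the value but never the argmax.
    Deterministic given the draws.
    """
    sll = _sll_from_logdraws(censored.log_draws(), params.alpha, censored.m)
    if log_region_constants is not None:
        sll += float(np.sum(log_region_constants))
    return sll


def _sll_from_logdraws(logW: np.ndarray, alpha: np.ndarray, m: int) -> float:
    """SLL kernel: logW is (N, m, n) log-draws."""
    logf = logW @ (alpha - 1.0) - _log_beta(alpha)  # (N, m)
    return float(np.sum(logsumexp(logf, axis=1)) - logf.shape[0] * math.log(m))


def fit_sml(
    spaces: Sequence[FeasibleWeightSpace] | None = None,
    m: int = 500,
    seed: int = 0,
    init: DirichletParams | None = None,
    *,
    censored: CensoredSample | None = None,
    log_region_constants: np.ndarray | None = None,
    return_details: bool = False,
) -> DirichletParams | tuple[DirichletParams, dict]:
    """Fit the Dirichlet model to region-censored data by SML.

    Draws ``m`` uniform vectors per region once (or accepts a prebuilt
    :class:`CensoredSample`), then maximizes the simulated log-likelihood
    with a quasi-Newton optimizer in the same unconstrained coordinates as
    the exact-data fit.  Initialization defaults to the centroid-based fit
    on the same draws.  The returned parameters attain an SLL at least as
    high as the initializer's.
    """
    if censored is None:
        if spaces is None:
            raise ValueError("provide either spaces or a CensoredSample")
        censored = build_censored_sample(spaces, m, seed)
    logW = censored.log_draws()
    mm = censored.m
    const = float(np.sum(log_region_constants)) if log_region_constants is not None else 0.0

    if init is None:
        if censored.N >= 2:
            init = fit_mle(censored.centroids())
        else:  # a single region: start from the pooled spread of its draws
            init = moment_estimate(censored.draws.reshape(-1, censored.n))

    def neg_sll(theta: np.ndarray) -> float:
        mu, phi = _unpack(theta)
        v = -(_sll_from_logdraws(logW, phi * mu, mm) + const)
        return v if np.isfinite(v) else 1e300  # overflow guard for the line search

    theta0 = _pack(init.mu, init.phi)
    res = minimize(neg_sll, theta0, method="L-BFGS-B")
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"SML fit did not converge: {res.message}")
    theta = res.x if res.fun <= neg_sll(theta0) else theta0
    mu, phi = _unpack(theta)
    params = DirichletParams(mu=mu, phi=phi)
    if return_details:
        details = {
            "sll": -float(res.fun) if res.fun <= neg_sll(theta0) else -neg_sll(theta0),
            "iterations": int(res.nit),
            "m": mm,
            "N": censored.N,
            "seed": censored.seed,
            "converged": bool(res.success),
        }
        return params, details
    return params


def fit_centroid(
    spaces: Sequence[FeasibleWeightSpace] | None = None,
    m: int = 500,
    seed: int = 0,
    *,
    censored: CensoredSample | None = None,
) -> DirichletParams:
    """Naive baseline: exact Dirichlet MLE on the regions' MC centroids.

    Treats each respondent's region centroid as if it were the exactly
    observed weight vector, discarding all within-region uncertainty.
    """
    if censored is None:
        if spaces is None:
            raise ValueError("provide either spaces or a CensoredSample")
        censored = build_censored_sample(spaces, m, seed)
    return fit_mle(censored.centroids())
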