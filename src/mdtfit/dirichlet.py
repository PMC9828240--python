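"""Dirichlet population model in mean-precision form.

Respondents' weight vectors are modelled as i.i.d. Dirichlet on the unit
simplex with density ``f(w) = (1 / B(alpha)) * prod_i w_i^(alpha_i - 1)``.
The parameter vector is written ``alpha = phi * mu`` with mean ``mu`` on the
simplex and precision ``phi > 0``; larger ``phi`` concentrates the
distribution around its mean (component variances are
``mu_i (1 - mu_i) / (phi + 1)``).

This module provides the density, sampling, and classical maximum
likelihood fitting to exactly observed weight vectors.  The fit runs a
quasi-Newton optimizer on unconstrained coordinates — a multinomial-logit
transform of ``mu`` and ``log phi`` — starting from the method-of-moments
estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .scales import as_weights

__all__ = ["DirichletParams", "log_density", "sample", "fit_mle", "clamp_interior"]

logger = logging.getLogger(__name__)

#: Weight components are clamped to at least this value before taking logs.
INTERIOR_EPS = 1e-12


@dataclass(frozen=True)
class DirichletParams:
    """Mean-precision parameterization: ``alpha = phi * mu``."""

    mu: np.ndarray
    phi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", as_weights(self.mu))
        if not self.phi > 0:
            raise ValueError(f"precision must be positive, got {self.phi}")

    @property
    def alpha(self) -> np.ndarray:
        return self.phi * self.mu

    @property
    def n(self) -> int:
        return self.mu.size

    def to_json(self) -> str:
        import json

        return json.dumps({"mu": self.mu.tolist(), "phi": self.phi})

    @classmethod
    def from_json(cls, s: str) -> "DirichletParams":
        import json

        d = json.loads(s)
        return cls(mu=np.asarray(d["mu"], dtype=float), phi=float(d["phi"]))


def clamp_interior(W: np.ndarray, eps: float = INTERIOR_EPS) -> np.ndarray:
    """Push weight vectors off the simplex boundary and renormalize.

    The Dirichlet density is zero or unbounded on the boundary; clamping at
    ``eps`` keeps log-densities finite without measurably moving interior
    points.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < eps):
        logger.warning("clamping %d boundary weight component(s) to %g",
                       int(np.sum(W < eps)), eps)
    W = np.clip(W, eps, None)
    return W / W.sum(axis=-1, keepdims=True)


def _log_beta(alpha: np.ndarray) -> float:
    """Log of the multinomial beta function B(alpha)."""
    return float(gammaln(alpha).sum() - gammaln(alpha.sum()))


def log_density(params: DirichletParams, w: Sequence[float]) -> float:
    """Log Dirichlet density at a single weight vector."""
    w = clamp_interior(np.asarray(w, dtype=float))
    if w.shape != (params.n,):
        raise ValueError(f"expected weight vector of length {params.n}")
    a = params.alpha
    return float((a - 1.0) @ np.log(w) - _log_beta(a))


def log_density_many(params: DirichletParams, W: np.ndarray) -> np.ndarray:
    """Vectorized :func:`log_density` over the rows of ``W``."""
    W = clamp_interior(np.asarray(W, dtype=float))
    a = params.alpha
    return np.log(W) @ (a - 1.0) - _log_beta(a)


def sample(
    params: DirichletParams, count: int, seed: int | np.random.Generator
) -> np.ndarray:
    """``count`` independent draws, as a ``(count, n)`` array."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(params.alpha, size=count)


# ----------------------------------------------------------------------
# maximum likelihood on exactly observed weight vectors
# ----------------------------------------------------------------------

def _unpack(theta: np.ndarray) -> tuple[np.ndarray, float]:
    """theta = (z_1..z_{n-1}, log phi) -> (mu, phi) via multinomial logit."""
    z = np.append(theta[:-1], 0.0)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum(), float(np.exp(min(theta[-1], 700.0)))


def _pack(mu: np.ndarray, phi: float) -> np.ndarray:
    logmu = np.log(np.clip(mu, 1e-300, None))
    return np.append(logmu[:-1] - logmu[-1], np.log(phi))


def moment_estimate(W: np.ndarray) -> DirichletParams:
    """Method-of-moments initializer for the Dirichlet fit."""
    W = np.asarray(W, dtype=float)
    mu = W.mean(axis=0)
    v = W.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_per = mu * (1.0 - mu) / v - 1.0
    phi_per = phi_per[np.isfinite(phi_per) & (phi_per > 0)]
    phi = float(np.clip(np.mean(phi_per) if phi_per.size else 1.0, 1e-2, 1e8))
    return DirichletParams(mu=clamp_interior(mu), phi=phi)


def fit_mle(weights: Sequence[Sequence[float]]) -> DirichletParams:
    """Exact Dirichlet maximum likelihood fit to observed weight vectors.

    Maximizes the log-likelihood through its sufficient statistic (the mean
    of the componentwise log-weights) over the transformed parameters,
    initialized at the method-of-moments estimate.  The returned parameters
    always attain a log-likelihood at least as high as the initializer's.
    """
    W = clamp_interior(np.asarray(weights, dtype=float))
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need at least 2 weight vectors")
    N, n = W.shape
    mean_log = np.log(W).mean(axis=0)

    def negll(theta: np.ndarray) -> float:
        mu, phi = _unpack(theta)
        a = phi * mu
        v = _log_beta(a) - float((a - 1.0) @ mean_log)  # per-observation
        return v if np.isfinite(v) else 1e300  # overflow guard for the line search

    init = moment_estimate(W)
    theta0 = _pack(init.mu, init.phi)
    res = minimize(negll, theta0, method="L-BFGS-B")
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"Dirichlet MLE did not converge: {res.message}")
    # L-BFGS-B cannot end above its own starting point, but guard anyway
    theta = res.x if res.fun <= negll(theta0) else theta0
    mu, phi = _unpack(theta)
    return DirichletParams(mu=mu, phi=phi)
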