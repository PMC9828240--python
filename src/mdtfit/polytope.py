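"""Feasible weight spaces: convex regions of the unit simplex.

An elicitation exercise ends with the knowledge that a respondent's weight
vector lies in a region Omega of the unit simplex cut out by homogeneous
linear inequalities (ranking constraints ``w_i - w_j >= 0`` and weight-ratio
bounds ``w_i - c w_j >= 0``).  This module represents such regions, tests
membership, draws asymptotically uniform samples with hit-and-run, and
estimates Monte Carlo centroids and volume fractions.

Sampling operates in the (n-1)-dimensional affine coordinates of the simplex
(the last weight is ``1 - sum`` of the others) so that the region has a
full-dimensional interior, which hit-and-run requires.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import linprog

__all__ = [
    "FeasibleWeightSpace",
    "full_simplex",
    "ranking_cone",
    "sample_uniform_simplex",
]

#: Membership tolerance: constraints may be violated by at most this amount.
CONTAINS_TOL = 1e-12

#: Default burn-in is this factor times the sampling dimension (n - 1).
BURN_IN_PER_DIM = 100


class FeasibleWeightSpace:
    """A convex region of the unit simplex defined by homogeneous half-spaces.

    Parameters
    ----------
    n:
        Number of attributes (simplex dimension + 1).
    constraints:
        Array of shape ``(k, n)``; each row ``a`` encodes ``a . w >= 0``.
        The simplex itself (``w >= 0``, ``sum w = 1``) is always implied and
        never listed.
    """

    def __init__(self, n: int, constraints: Sequence[Sequence[float]] | None = None):
        if n < 2:
            raise ValueError("need at least 2 attributes")
        self.n = int(n)
        A = np.asarray(constraints, dtype=float) if constraints is not None else np.empty((0, n))
        if A.size == 0:
            A = A.reshape(0, n)
        if A.ndim != 2 or A.shape[1] != n:
            raise ValueError(f"constraints must have shape (k, {n})")
        self.A = A
        self._interior_point: np.ndarray | None = None

    # ------------------------------------------------------------------
    # membership
    # ------------------------------------------------------------------
    def contains(self, w: Sequence[float], *, tol: float = CONTAINS_TOL) -> bool:
        """True iff ``w`` is on the simplex and satisfies every constraint."""
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n,):
            raise ValueError(f"expected a weight vector of length {self.n}")
        if np.any(w < -tol) or abs(w.sum() - 1.0) > 1e-9:
            return False
        return bool(np.all(self.A @ w >= -tol)) if len(self.A) else True

    def contains_many(self, W: np.ndarray, *, tol: float = CONTAINS_TOL) -> np.ndarray:
        """Vectorized :meth:`contains` for an ``(m, n)`` array of vectors."""
        W = np.asarray(W, dtype=float)
        ok = np.all(W >= -tol, axis=1) & (np.abs(W.sum(axis=1) - 1.0) <= 1e-9)
        if len(self.A):
            ok &= np.all(W @ self.A.T >= -tol, axis=1)
        return ok

    def intersect(self, other: "FeasibleWeightSpace") -> "FeasibleWeightSpace":
        if other.n != self.n:
            raise ValueError("dimension mismatch")
        return FeasibleWeightSpace(self.n, np.vstack([self.A, other.A]))

    # ------------------------------------------------------------------
    # reduced (n-1)-dimensional inequality form  G y <= h,  w = (y, 1 - sum y)
    # ------------------------------------------------------------------
    def reduced_inequalities(self) -> tuple[np.ndarray, np.ndarray]:
        n, d = self.n, self.n - 1
        rows = [-np.eye(d), np.ones((1, d))]        # y >= 0,  sum y <= 1
        rhs = [np.zeros(d), np.ones(1)]
        if len(self.A):
            # a.w >= 0  ->  -(a[:d] - a[d]) . y <= a[d]
            G = -(self.A[:, :d] - self.A[:, d:])
            rows.append(G)
            rhs.append(self.A[:, d])
        return np.vstack(rows), np.concatenate(rhs)

    def interior_point(self) -> np.ndarray:
        """Chebyshev center of the reduced inequality system (cached).

        Raises
        ------
        ValueError
            If the inequality system has no interior, with the offending
            constraint matrix in the message.
        """
        if self._interior_point is None:
            G, h = self.reduced_inequalities()
            norms = np.linalg.norm(G, axis=1)
            # maximize r  s.t.  G y + ||g_k|| r <= h
            res = linprog(
                c=np.r_[np.zeros(self.n - 1), -1.0],
                A_ub=np.c_[G, norms],
                b_ub=h,
                bounds=[(None, None)] * (self.n - 1) + [(0, None)],
                method="highs",
            )
            if not res.success or res.x[-1] <= 0:
                raise ValueError(
                    "feasible weight space has empty interior; constraint "
                    f"rows (a.w >= 0):\n{self.A}"
                )
            self._interior_point = res.x[:-1]
        return self._interior_point

    # ------------------------------------------------------------------
    # sampling
    # ------------------------------------------------------------------
    def hit_and_run_sample(
        self,
        m: int,
        seed: int | np.random.Generator,
        *,
        burn_in: int | None = None,
        thin: int = 1,
    ) -> np.ndarray:
        """Draw ``m`` asymptotically uniform samples from the region.

        Runs a single hit-and-run chain started at the Chebyshev center of
        the region, discards ``burn_in`` states (default
        ``100 * (n - 1)``) and keeps every ``thin``-th state thereafter.
        Returns an ``(m, n)`` array of weight vectors, each summing to 1.
        """
        if m < 1:
            raise ValueError("m must be >= 1")
        if burn_in is None:
            burn_in = BURN_IN_PER_DIM * (self.n - 1)
        rng = np.random.default_rng(seed)
        G, h = self.reduced_inequalities()
        y0 = self.interior_point()
        T = burn_in + m * thin
        dirs = rng.standard_normal((T, self.n - 1))
        unifs = rng.random(T)
        ys = _hit_and_run_chain(G, h, y0, dirs, unifs, burn_in)[::thin][:m]
        W = np.empty((m, self.n))
        W[:, :-1] = ys
        W[:, -1] = 1.0 - ys.sum(axis=1)
        np.clip(W, 0.0, None, out=W)
        return W / W.sum(axis=1, keepdims=True)

    def centroid(self, m: int, seed: int | np.random.Generator) -> np.ndarray:
        """Monte Carlo centroid: mean of ``m`` hit-and-run samples."""
        W = self.hit_and_run_sample(m, seed)
        c = W.mean(axis=0)
        return c / c.sum()

    def volume_fraction(self, m: int, seed: int | np.random.Generator) -> float:
        """Accept-reject estimate of vol(region) / vol(simplex).

        Used only for diagnostics and oracle tests; the simulated
        likelihood never needs it.
        """
        W = sample_uniform_simplex(self.n, m, seed)
        return float(self.contains_many(W).mean())

    # ------------------------------------------------------------------
    # serialization (debugging aid)
    # ------------------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"n": self.n, "constraints": self.A.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "FeasibleWeightSpace":
        d = json.loads(s)
        return cls(d["n"], d["constraints"])

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeasibleWeightSpace(n={self.n}, k={len(self.A)} constraints)"


def full_simplex(n: int) -> FeasibleWeightSpace:
    """The unconstrained unit simplex on ``n`` attributes."""
    return FeasibleWeightSpace(n)


def ranking_cone(ranking: Sequence[int], n: int) -> FeasibleWeightSpace:
    """Cone ``w_{r_0} >= w_{r_1} >= ... >= w_{r_{n-1}}`` for a ranking."""
    ranking = list(ranking)
    if sorted(ranking) != list(range(n)):
        raise ValueError(f"ranking must be a permutation of 0..{n - 1}")
    A = np.zeros((n - 1, n))
    for k in range(n - 1):
        A[k, ranking[k]] = 1.0
        A[k, ranking[k + 1]] = -1.0
    return FeasibleWeightSpace(n, A)


def sample_uniform_simplex(
    n: int, m: int, seed: int | np.random.Generator
) -> np.ndarray:
    """``m`` exact uniform draws from the unit simplex (flat Dirichlet)."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(n), size=m)


@njit(cache=False)
def _hit_and_run_chain(G, h, y0, dirs, unifs, burn_in):
    """Hit-and-run chain over ``{y : G y <= h}`` with pre-drawn randomness.

    ``dirs`` are standard-normal directions (isotropic after normalization,
    which the chord computation does not require) and ``unifs`` the uniform
    positions along each chord.  Returns the states after burn-in.
    """
    T, d = dirs.shape
    out = np.empty((T - burn_in, d))
    y = y0.copy()
    k = G.shape[0]
    for t in range(T):
        delta = dirs[t]
        t_lo, t_hi = -1e300, 1e300
        for i in range(k):
            a = 0.0
            gy = 0.0
            for j in range(d):
                a += G[i, j] * delta[j]
                gy += G[i, j] * y[j]
            b = h[i] - gy
            if a > 1e-14:
                v = b / a
                if v < t_hi:
                    t_hi = v
            elif a < -1e-14:
                v = b / a
                if v > t_lo:
                    t_lo = v
        # numerical safety at the boundary: the chord always includes 0
        if t_lo > 0.0:
            t_lo = 0.0
        if t_hi < 0.0:
            t_hi = 0.0
        step = t_lo + unifs[t] * (t_hi - t_lo)
        for j in range(d):
            y[j] = y[j] + step * delta[j]
        if t >= burn_in:
            for j in range(d):
                out[t - burn_in, j] = y[j]
    return out
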