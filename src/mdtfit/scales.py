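"""Attribute scales, partial value functions, and the additive value model.

Treatment alternatives are scored with a weighted additive value function

    v(x) = sum_i  w_i * v_i(x_i),

where each partial value function ``v_i`` maps an attribute's natural
measurement scale onto a 0-to-1 scale of increasing preference (worst level
to 0, best level to 1) and the weights ``w`` lie on the unit simplex.  All
partial value functions are linear, so the marginal rate of substitution
between attributes is constant and the weights are the only preference
parameters.

Harm attributes are expressed with ``worst > best`` on the natural scale;
the single interpolation formula ``(x - worst) / (best - worst)`` then
yields a decreasing map without a separate code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AttributeScale",
    "as_weights",
    "partial_value",
    "level_for_partial_value",
    "additive_value",
    "question_ratio_threshold",
]

#: Tolerance on the weight-sum constraint.
WEIGHT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class AttributeScale:
    """An attribute's natural scale range and implied preference direction.

    Parameters
    ----------
    name:
        Attribute label, e.g. ``"PFS"``.
    worst:
        Least preferred level on the natural scale (partial value 0).
    best:
        Most preferred level on the natural scale (partial value 1).
        ``best < worst`` denotes a harm (decreasing preference in the
        natural units); ``best > worst`` a benefit.
    """

    name: str
    worst: float
    best: float

    def __post_init__(self) -> None:
        if self.worst == self.best:
            raise ValueError(
                f"attribute {self.name!r}: worst and best levels must differ"
            )

    @property
    def direction(self) -> int:
        """+1 for increasing (benefit) attributes, -1 for decreasing (harm)."""
        return 1 if self.best > self.worst else -1

    @property
    def lo(self) -> float:
        return min(self.worst, self.best)

    @property
    def hi(self) -> float:
        return max(self.worst, self.best)


def as_weights(w: Sequence[float], *, tol: float = WEIGHT_SUM_TOL) -> np.ndarray:
    """Validate and renormalize a weight vector on the unit simplex.

    Components must be nonnegative and sum to 1 within ``tol``; the returned
    array is renormalized to sum exactly to 1.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("weight vector must be 1-d with at least 2 components")
    if np.any(w < 0):
        raise ValueError(f"weights must be nonnegative, got {w}")
    s = w.sum()
    if abs(s - 1.0) > tol:
        raise ValueError(f"weights must sum to 1 within {tol}, got sum {s}")
    return w / s


def partial_value(scale: AttributeScale, x: float) -> float:
    """Linear partial value of level ``x``: 0 at ``worst``, 1 at ``best``."""
    if not (scale.lo <= x <= scale.hi):
        raise ValueError(
            f"level {x} outside the range [{scale.lo}, {scale.hi}] of "
            f"attribute {scale.name!r}"
        )
    return (x - scale.worst) / (scale.best - scale.worst)


def level_for_partial_value(scale: AttributeScale, v: float) -> float:
    """Natural-scale level whose partial value is ``v`` (inverse of
    :func:`partial_value`)."""
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"partial value {v} outside [0, 1]")
    return scale.worst + v * (scale.best - scale.worst)


def additive_value(
    w: Sequence[float],
    scales: Sequence[AttributeScale],
    levels: Sequence[float],
) -> float:
    """Additive value of an alternative: the weight-sum of partial values.

    Returns 0 for the all-worst alternative and 1 for the all-best one.
    """
    w = as_weights(w)
    levels = np.asarray(levels, dtype=float)
    if not (len(scales) == w.size == levels.size):
        raise ValueError(
            f"dimension mismatch: {w.size} weights, {len(scales)} scales, "
            f"{levels.size} levels"
        )
    return float(
        sum(wi * partial_value(s, x) for wi, s, x in zip(w, scales, levels))
    )


def question_ratio_threshold(scale_i: AttributeScale, t: float) -> float:
    """Weight ratio ``w_i / w_j`` at which a thresholding question is tied.

    In a thresholding question between attribute ``i`` (improving) and the
    next-ranked attribute ``j``, the reference alternative has worst ``i``
    and best ``j``, the target has level ``t`` on ``i`` and worst ``j``
    (everything else equal).  Indifference occurs exactly on the hyperplane
    ``w_i / w_j = 1 / v_i(t)``, which this function returns.
    """
    v = partial_value(scale_i, t)
    if v <= 0.0:
        raise ValueError(
            f"level {t} has zero partial value on {scale_i.name!r}: the "
            "indifference ratio is infinite"
        )
    return 1.0 / v
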