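"""Multi-dimensional thresholding (MDT): simulated questioning and geometry.

MDT elicits attribute weights in two phases.  A swing-ranking phase orders
the attributes by which worst-to-best improvement the respondent would take
first, pinning the weight vector to a ranking cone of the simplex.  A
thresholding phase then sharpens each consecutive pair (i, j) in the ranking
with a short bisection: each question offers a reference alternative (worst
on i, best on j) against a target (intermediate level on i, worst on j),
and the answer reveals on which side of a hyperplane ``w_i / w_j = const``
the respondent lies.  After ``s`` questions the ratio ``w_i / w_j`` is
bracketed between a lower and an upper bound, and the respondent's feasible
weight space is the intersection of the ranking cone with all ratio bounds.

The simulated respondent here answers deterministically from a known weight
vector and linear partial value functions, with no response error; exact
indifference resolves to the reference alternative (a measure-zero event
under any continuous population model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Iterator, Sequence

import numpy as np

from .polytope import FeasibleWeightSpace
from .scales import (
    AttributeScale,
    additive_value,
    as_weights,
    level_for_partial_value,
)

__all__ = [
    "ResponseRecord",
    "TradeoffBounds",
    "swing_ranking",
    "simulate_thresholding",
    "run_mdt",
    "space_from_record",
    "enumerate_paths",
    "iter_paths",
    "total_questions",
]


@dataclass(frozen=True)
class ResponseRecord:
    """Raw output of one respondent's MDT exercise.

    ``ranking`` lists attribute indices from most to least important;
    ``choices`` holds, for each consecutive-pair trade-off in ranking
    order, the bisection answers (``True`` = target chosen).
    """

    ranking: tuple[int, ...]
    choices: tuple[tuple[bool, ...], ...]
    id: str = ""

    def __post_init__(self) -> None:
        n = len(self.ranking)
        if sorted(self.ranking) != list(range(n)):
            raise ValueError(f"ranking {self.ranking} is not a permutation of 0..{n - 1}")
        if len(self.choices) > n - 1:
            raise ValueError("more choice lists than consecutive-pair trade-offs")


@dataclass(frozen=True)
class TradeoffBounds:
    """Bisection bracket ``lower <= w_i / w_j <= upper`` for a ranked pair."""

    pair: tuple[int, int]
    lower: float
    upper: float  # math.inf when the ratio is unbounded above

    def __post_init__(self) -> None:
        if not (1.0 <= self.lower < self.upper):
            raise ValueError(f"invalid bounds [{self.lower}, {self.upper}]")


def swing_ranking(w: Sequence[float]) -> tuple[int, ...]:
    """Attribute indices by descending weight (the order of preferred swings).

    With linear partial value functions the most-wanted worst-to-best swing
    is always the attribute with the largest weight, so the simulated swing
    ranking reduces to a sort.  Exact ties break by ascending index.
    """
    w = as_weights(w)
    return tuple(int(i) for i in np.argsort(-w, kind="stable"))


def simulate_thresholding(
    w: Sequence[float],
    scales: Sequence[AttributeScale],
    pair: tuple[int, int],
    steps: int,
) -> tuple[tuple[bool, ...], TradeoffBounds]:
    """Run the bisection for one trade-off and return the answers and bounds.

    The bisection lives on the partial-value scale of attribute ``i``: the
    bracket starts at [0, 1] and question ``k`` poses the target at the
    natural level whose partial value is the bracket midpoint (for the PFS
    scale 50-90 that is level 70, then 80 or 60, ...).  A respondent with
    ratio ``w_i / w_j`` above the question's threshold prefers the target,
    which narrows the bracket to its lower half; otherwise to its upper
    half.  The true ratio always ends inside the returned bounds.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1 (use run_mdt with steps=0 for ranking only)")
    w = as_weights(w)
    i, j = pair
    if w[i] < w[j]:
        raise ValueError(f"pair ({i}, {j}) must be ordered by the ranking (w_i >= w_j)")
    n = len(scales)

    best = np.array([s.best for s in scales])
    reference = best.copy()
    reference[i] = scales[i].worst
    target = best.copy()
    target[j] = scales[j].worst

    v_lo, v_hi = 0.0, 1.0
    answers: list[bool] = []
    for _ in range(steps):
        v_mid = 0.5 * (v_lo + v_hi)
        target[i] = level_for_partial_value(scales[i], v_mid)
        target_chosen = additive_value(w, scales, target) > additive_value(w, scales, reference)
        answers.append(target_chosen)
        if target_chosen:
            v_hi = v_mid
        else:
            v_lo = v_mid
    bounds = TradeoffBounds(
        pair=(i, j),
        lower=1.0 / v_hi,
        upper=math.inf if v_lo == 0.0 else 1.0 / v_lo,
    )
    return tuple(answers), bounds


def _bounds_from_choices(pair: tuple[int, int], answers: Sequence[bool]) -> TradeoffBounds:
    """Replay a recorded bisection to recover the ratio bounds."""
    v_lo, v_hi = 0.0, 1.0
    for target_chosen in answers:
        v_mid = 0.5 * (v_lo + v_hi)
        if target_chosen:
            v_hi = v_mid
        else:
            v_lo = v_mid
    return TradeoffBounds(
        pair=pair,
        lower=1.0 / v_hi,
        upper=math.inf if v_lo == 0.0 else 1.0 / v_lo,
    )


def _space_from_parts(
    n: int,
    ranking: Sequence[int],
    bounds: Sequence[TradeoffBounds],
) -> FeasibleWeightSpace:
    rows = []
    for k in range(n - 1):  # ranking cone: w_{r_k} >= w_{r_{k+1}}
        a = np.zeros(n)
        a[ranking[k]], a[ranking[k + 1]] = 1.0, -1.0
        rows.append(a)
    for b in bounds:
        i, j = b.pair
        if b.lower > 1.0:  # w_i - lower * w_j >= 0 (lower == 1 is the cone row)
            a = np.zeros(n)
            a[i], a[j] = 1.0, -b.lower
            rows.append(a)
        if math.isfinite(b.upper):  # upper * w_j - w_i >= 0
            a = np.zeros(n)
            a[i], a[j] = -1.0, b.upper
            rows.append(a)
    return FeasibleWeightSpace(n, np.array(rows))


def run_mdt(
    w: Sequence[float],
    scales: Sequence[AttributeScale],
    steps_per_tradeoff: int,
    *,
    question_budget: int | None = None,
    respondent_id: str = "",
) -> tuple[ResponseRecord, FeasibleWeightSpace]:
    """Simulate a full MDT exercise for a respondent with known weights.

    Ranks the attributes by swing ranking, then bisects each consecutive
    pair in ranking order with ``steps_per_tradeoff`` questions.  An
    optional ``question_budget`` caps the total number of thresholding
    questions by dropping trailing trade-offs whole (a trade-off is either
    fully bisected or not asked).  Returns the response record together
    with the feasible weight space it induces; the true ``w`` is always
    contained in that space.
    """
    w = as_weights(w)
    n = len(scales)
    if w.size != n or n < 2:
        raise ValueError("need matching scales and weights for >= 2 attributes")
    if steps_per_tradeoff < 0:
        raise ValueError("steps_per_tradeoff must be >= 0")
    ranking = swing_ranking(w)

    n_tradeoffs = n - 1
    if question_budget is not None and steps_per_tradeoff > 0:
        n_tradeoffs = min(n_tradeoffs, question_budget // steps_per_tradeoff)

    choices: list[tuple[bool, ...]] = []
    all_bounds: list[TradeoffBounds] = []
    if steps_per_tradeoff > 0:
        for k in range(n_tradeoffs):
            pair = (ranking[k], ranking[k + 1])
            answers, bounds = simulate_thresholding(w, scales, pair, steps_per_tradeoff)
            choices.append(answers)
            all_bounds.append(bounds)
    record = ResponseRecord(ranking=ranking, choices=tuple(choices), id=respondent_id)
    return record, _space_from_parts(n, ranking, all_bounds)


def space_from_record(record: ResponseRecord, n: int) -> FeasibleWeightSpace:
    """Reconstruct a respondent's feasible weight space from the raw record.

    Pure function of the record: with linear partial value functions the
    ratio bounds depend only on the binary answers, so elicitation and
    fitting can run on different machines.
    """
    if len(record.ranking) != n:
        raise ValueError(f"record has {len(record.ranking)} attributes, expected {n}")
    bounds = [
        _bounds_from_choices((record.ranking[k], record.ranking[k + 1]), ans)
        for k, ans in enumerate(record.choices)
        if len(ans) > 0
    ]
    return _space_from_parts(n, record.ranking, bounds)


def enumerate_paths(n: int, steps_per_tradeoff: int) -> int:
    """Number of distinct paths through the questioning tree.

    Every path is a ranking permutation followed by an independent binary
    answer at each of the ``steps * (n - 1)`` thresholding questions:
    ``n! * 2**(steps * (n - 1))`` paths in total (96 for three attributes
    with two bisection steps per trade-off).
    """
    if n < 2 or steps_per_tradeoff < 0:
        raise ValueError("need n >= 2 and steps >= 0")
    return math.factorial(n) * 2 ** (steps_per_tradeoff * (n - 1))


def iter_paths(n: int, steps_per_tradeoff: int) -> Iterator[ResponseRecord]:
    """Yield the response record of every path through the questioning tree."""
    if n < 2 or steps_per_tradeoff < 0:
        raise ValueError("need n >= 2 and steps >= 0")
    answer_seqs = list(product((False, True), repeat=steps_per_tradeoff))
    for ranking in permutations(range(n)):
        for combo in product(answer_seqs, repeat=n - 1):
            yield ResponseRecord(ranking=ranking, choices=combo)


def total_questions(n: int, steps_per_tradeoff: int) -> int:
    """Thresholding questions asked after the ranking phase:
    ``(n - 1) * steps_per_tradeoff``."""
    if n < 2 or steps_per_tradeoff < 0:
        raise ValueError("need n >= 2 and steps >= 0")
    return (n - 1) * steps_per_tradeoff
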