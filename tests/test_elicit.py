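"""The simulated MDT questioning procedure and its induced geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdtfit import (
    ResponseRecord,
    enumerate_paths,
    iter_paths,
    run_mdt,
    simulate_thresholding,
    space_from_record,
    swing_ranking,
    total_questions,
    unit_scales,
)

W_EXAMPLE = np.array([0.5, 0.2, 0.3])


class TestSwingRanking:
    @pytest.mark.parametrize(
        "w, expected",
        [
            ((0.5, 0.2, 0.3), (0, 2, 1)),    # PFS > ST > MT
            ((1 / 3, 1 / 3, 1 / 3), (0, 1, 2)),  # ties break by index
            ((0.1, 0.6, 0.3), (1, 2, 0)),
        ],
    )
    def test_orders_by_descending_weight(self, w, expected):
        assert swing_ranking(w) == expected


class TestSimulateThresholding:
    def test_worked_example_two_steps(self, myeloma_scales):
        """Reference chosen at the 70%-PFS question (ratio 5/3 < 2), target
        at the 80%-PFS question (5/3 > 4/3): bounds [4/3, 2]."""
        answers, bounds = simulate_thresholding(W_EXAMPLE, myeloma_scales, (0, 2), 2)
        assert answers == (False, True)
        assert bounds.lower == pytest.approx(4 / 3)
        assert bounds.upper == pytest.approx(2.0)

    def test_third_step_narrows_to_1p6(self, myeloma_scales):
        """Third question sits at partial value 0.625 (75% PFS, threshold
        1.6); the true ratio 5/3 exceeds it, so the bracket ends [1.6, 2]."""
        answers, bounds = simulate_thresholding(W_EXAMPLE, myeloma_scales, (0, 2), 3)
        assert answers == (False, True, True)
        assert bounds.lower == pytest.approx(1.6)
        assert bounds.upper == pytest.approx(2.0)

    def test_equal_weights_always_choose_reference(self, myeloma_scales):
        """At ratio exactly 1 the target is never strictly preferred, so the
        lower bound stays 1 and the upper bound is 1/(1 - 2^-s)."""
        answers, bounds = simulate_thresholding((0.4, 0.2, 0.4), myeloma_scales, (0, 2), 4)
        assert answers == (False,) * 4
        assert bounds.lower == pytest.approx(1.0)
        assert bounds.upper == pytest.approx(1.0 / (1.0 - 2.0**-4))

    def test_true_ratio_always_inside_bounds(self, myeloma_scales, rng):
        for _ in range(200):
            w = rng.dirichlet(np.ones(3))
            i, j = swing_ranking(w)[:2]
            steps = int(rng.integers(1, 4))
            _, b = simulate_thresholding(w, myeloma_scales, (i, j), steps)
            assert b.lower <= w[i] / w[j] <= b.upper

    def test_zero_steps_rejected(self, myeloma_scales):
        with pytest.raises(ValueError, match="steps"):
            simulate_thresholding(W_EXAMPLE, myeloma_scales, (0, 2), 0)

    def test_misordered_pair_rejected(self, myeloma_scales):
        with pytest.raises(ValueError, match="ordered"):
            simulate_thresholding(W_EXAMPLE, myeloma_scales, (1, 0), 2)


class TestRunMdt:
    def test_worked_example_record_and_containment(self, myeloma_scales):
        record, space = run_mdt(W_EXAMPLE, myeloma_scales, 2)
        assert record.ranking == (0, 2, 1)
        assert record.choices == ((False, True), (False, True))
        assert space.contains(W_EXAMPLE)

    def test_zero_steps_gives_ranking_cone(self, myeloma_scales):
        record, space = run_mdt(W_EXAMPLE, myeloma_scales, 0)
        assert record.choices == ()
        assert space.A.shape == (2, 3)  # two ordering constraints only
        assert space.contains(W_EXAMPLE)
        assert not space.contains(np.array([0.2, 0.5, 0.3]))

    def test_containment_over_many_respondents(self, myeloma_scales, rng):
        """The true weight vector satisfies every emitted constraint."""
        scales4 = unit_scales(4)
        for k in range(1000):
            n = 3 if k % 2 == 0 else 4
            scales = myeloma_scales if n == 3 else scales4
            w = rng.dirichlet(np.ones(n))
            steps = 1 + k % 3
            _, space = run_mdt(w, scales, steps)
            assert space.contains(w)

    def test_question_budget_truncates_whole_tradeoffs(self):
        scales = unit_scales(4)
        w = (0.4, 0.3, 0.2, 0.1)
        record, _ = run_mdt(w, scales, 2, question_budget=3)
        assert len(record.choices) == 1  # 3 // 2 = 1 full trade-off
        record, _ = run_mdt(w, scales, 2, question_budget=4)
        assert len(record.choices) == 2

    def test_refinement_nests_feasible_spaces(self, myeloma_scales, rng):
        """One more bisection step can only shrink the feasible space."""
        for seed in range(5):
            w = np.random.default_rng(seed).dirichlet(np.ones(3))
            _, coarse = run_mdt(w, myeloma_scales, 1)
            _, fine = run_mdt(w, myeloma_scales, 2)
            samples = fine.hit_and_run_sample(200, rng)
            assert coarse.contains_many(samples).all()


class TestReconstruction:
    def test_space_from_record_matches_elicitation(self, myeloma_scales, rng):
        """Record -> space is a pure function reproducing the elicited
        constraint set exactly."""
        for seed in range(20):
            w = np.random.default_rng(seed).dirichlet(np.ones(3))
            record, space = run_mdt(w, myeloma_scales, 2)
            rebuilt = space_from_record(record, 3)
            assert np.array_equal(space.A, rebuilt.A)

    def test_dimension_check(self):
        record = ResponseRecord(ranking=(0, 1, 2), choices=())
        with pytest.raises(ValueError, match="expected"):
            space_from_record(record, 4)


class TestQuestioningTree:
    @pytest.mark.parametrize(
        "n, steps, expected",
        [(3, 2, 96), (3, 0, 6), (4, 3, 12288)],
    )
    def test_path_counts(self, n, steps, expected):
        assert enumerate_paths(n, steps) == expected

    @pytest.mark.parametrize("n, steps", [(3, 2), (4, 1)])
    def test_count_matches_exhaustive_walk(self, n, steps):
        records = list(iter_paths(n, steps))
        assert len(records) == enumerate_paths(n, steps)
        assert len(set(records)) == len(records)

    def test_paths_partition_the_simplex(self, rng):
        """A random weight vector falls in exactly one path's space."""
        spaces = [space_from_record(r, 3) for r in iter_paths(3, 2)]
        for _ in range(200):
            w = rng.dirichlet(np.ones(3))
            hits = sum(s.contains(w) for s in spaces)
            assert hits == 1

    @pytest.mark.parametrize("n, steps, expected", [(4, 3, 9), (6, 3, 15), (5, 0, 0)])
    def test_total_questions(self, n, steps, expected):
        assert total_questions(n, steps) == expected

    @settings(derandomize=True, max_examples=30)
    @given(n=st.integers(2, 6), steps=st.integers(0, 4))
    def test_counting_formula(self, n, steps):
        assert enumerate_paths(n, steps) == math.factorial(n) * 2 ** (steps * (n - 1))
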