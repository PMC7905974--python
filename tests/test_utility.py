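"""Reward-penalty marginal utilities and additive ranking invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmhrank import (
    ImpactVector,
    LevelVector,
    ParameterError,
    UtilityParams,
    ValidationError,
    marginal_utility,
    marginal_utility_matrix,
    overall_utility,
    rank_activities,
    rank_for_levels,
    round_half_up,
)
from pmhrank.questionnaire import FACTORS

levels_st = st.floats(min_value=0.0, max_value=3.0, allow_nan=False)


def _vec(cid, values):
    return LevelVector(cid, dict(zip(FACTORS, values)))


class TestMarginalUtility:
    @pytest.mark.parametrize(
        ("level", "impact", "expected"),
        [
            (1.76, +1, 2.24),   # reward: k_pos - level
            (3.00, -1, 0.00),   # neutral: factor already satisfied
            (1.36, -1, -1.64),  # penalty: level - k_neg
            (0.00, +1, 4.00),   # maximum reward at zero competence
            (0.00, -1, -3.00),  # worst penalty at zero competence
        ],
    )
    def test_branch_values(self, level, impact, expected, params):
        assert marginal_utility(level, impact, params) == pytest.approx(expected)

    def test_level_out_of_range(self, params):
        with pytest.raises(ValidationError):
            marginal_utility(3.1, 1, params)
        with pytest.raises(ValidationError):
            marginal_utility(1.0, 0, params)

    @settings(derandomize=True)
    @given(level=levels_st, impact=st.sampled_from([-1, 1]))
    def test_range_invariant(self, level, impact):
        p = UtilityParams()
        u = marginal_utility(level, impact, p)
        assert -p.k_negative <= u <= p.k_positive
        # the extremes are attained exactly at zero competence
        if level == 0.0:
            assert u == (p.k_positive if impact == 1 else -p.k_negative)

    @settings(derandomize=True)
    @given(a=levels_st, b=levels_st)
    def test_branch_monotonicity(self, a, b):
        p = UtilityParams()
        lo, hi = sorted((a, b))
        # improving impact: utility strictly decreases with competence
        assert marginal_utility(hi, 1, p) <= marginal_utility(lo, 1, p)
        if hi - lo > 1e-9:
            assert marginal_utility(hi, 1, p) < marginal_utility(lo, 1, p)
        # non-improving impact: non-decreasing, zero from the threshold up
        assert marginal_utility(hi, -1, p) >= marginal_utility(lo, -1, p)
        if lo >= p.neutral_threshold:
            assert marginal_utility(lo, -1, p) == 0.0

    def test_jump_at_neutral_threshold(self, params):
        """The penalty branch jumps to 0 at the threshold, by k_neg - threshold."""
        eps = 1e-9
        below = marginal_utility(params.neutral_threshold - eps, -1, params)
        at = marginal_utility(params.neutral_threshold, -1, params)
        assert at == 0.0
        jump = at - below
        assert jump == pytest.approx(params.k_negative - params.neutral_threshold, abs=1e-6)
        assert jump == pytest.approx(0.5, abs=1e-6)  # at the deployed calibration


class TestUtilityMatrix:
    def test_worked_example_matrix(self, fx, catalogue7, params):
        got = marginal_utility_matrix(
            fx["cohort_levels"]["User 3"], catalogue7, params
        ).marginals.map(lambda v: round_half_up(v, 2))
        assert got.equals(fx["worked_marginals"])

    def test_all_levels_three(self, catalogue7, params):
        m = marginal_utility_matrix(_vec("c", [3.0] * 6), catalogue7, params).marginals
        for a in catalogue7:
            for j, f in enumerate(FACTORS):
                assert m.loc[a.activity_id, f] == (1.0 if a.impacts[j] == 1 else 0.0)

    def test_all_levels_zero(self, catalogue7, params):
        m = marginal_utility_matrix(_vec("c", [0.0] * 6), catalogue7, params).marginals
        for a in catalogue7:
            for j, f in enumerate(FACTORS):
                expected = params.k_positive if a.impacts[j] == 1 else -params.k_negative
                assert m.loc[a.activity_id, f] == expected

    def test_duplicate_activity_ids(self, params):
        cat = [ImpactVector("R1A1", (1,) * 6), ImpactVector("R1A1", (1,) * 6)]
        with pytest.raises(ValidationError, match="duplicate"):
            marginal_utility_matrix(_vec("c", [1.0] * 6), cat, params)

    def test_overall_equals_row_sums(self, fx, catalogue7, params):
        m = marginal_utility_matrix(fx["cohort_levels"]["User 5"], catalogue7, params)
        assert np.allclose(m.overall.to_numpy(), m.marginals.sum(axis=1).to_numpy(), atol=1e-12)


class TestOverallUtility:
    def test_worked_example_sum(self):
        assert overall_utility([2.24, 0, 0, 2.46, 0, -1.64]) == pytest.approx(3.06)

    def test_zeros(self):
        assert overall_utility([0.0] * 6) == 0.0

    def test_hand_summed_case(self, fx, catalogue7, params):
        # User 11 x R7A1: (1.26-3)+(1.58-3)+(4-0)+(4-0.52)+(0.71-3)+(0.71-3)
        m = marginal_utility_matrix(fx["cohort_levels"]["User 11"], catalogue7, params)
        assert round_half_up(m.overall["R7A1"], 2) == -0.26

    def test_wrong_length(self):
        with pytest.raises(ValidationError):
            overall_utility([1.0, 2.0])


class TestRanking:
    def test_worked_example_top_two(self, fx, catalogue7, params):
        plan = rank_for_levels(fx["cohort_levels"]["User 3"], catalogue7, params)
        assert plan.activity_order[:2] == ("R9A3", "R1A1")
        assert round_half_up(plan.utility_of("R9A3"), 2) == 3.42

    def test_single_activity(self, params):
        cat = [ImpactVector("R1A1", (1, -1, -1, 1, -1, -1))]
        plan = rank_for_levels(_vec("c", [1.0] * 6), cat, params)
        assert plan.activity_order == ("R1A1",)
        assert list(plan.table["rank"]) == [1]

    def test_invalid_tie_break(self, fx, catalogue7, params):
        m = marginal_utility_matrix(fx["cohort_levels"]["User 1"], catalogue7, params)
        with pytest.raises(ParameterError):
            rank_activities(m, tie_break="random")

    def _random_plans(self, n_instances, n_activities=20, seed=1234):
        rng = np.random.default_rng(seed)
        ids = [f"R{i // 3 + 1}A{i % 3 + 1}" for i in range(n_activities)]
        for _ in range(n_instances):
            levels = _vec("c", rng.uniform(0, 3, 6))
            impacts = rng.choice([-1, 1], size=(n_activities, 6))
            impacts[:, 0] = 1  # every activity improves something
            cat = [ImpactVector(i, tuple(int(v) for v in row))
                   for i, row in zip(ids, impacts)]
            yield levels, cat

    def test_order_matches_oracle_sort(self, params):
        """Ranking equals an independent sort of (utility, id) pairs."""
        for levels, cat in self._random_plans(200):
            plan = rank_for_levels(levels, cat, params)
            m = marginal_utility_matrix(levels, cat, params)
            oracle = [
                a for a, _ in sorted(
                    ((a.activity_id, float(m.overall[a.activity_id])) for a in cat),
                    key=lambda t: (-t[1], [-ord(c) for c in t[0]]),
                )
            ]
            assert list(plan.activity_order) == oracle

    def test_sum_and_average_rank_identically(self, params):
        for levels, cat in self._random_plans(100, seed=77):
            m = marginal_utility_matrix(levels, cat, params)
            by_sum = rank_activities(m).activity_order
            avg = m.overall / 6.0
            oracle = sorted(avg.index, key=lambda a: (-avg[a], [-ord(c) for c in a]))
            assert list(by_sum) == oracle

    def test_weak_order_complete_and_transitive(self, params):
        for levels, cat in self._random_plans(50, seed=5):
            u = marginal_utility_matrix(levels, cat, params).overall
            ids = list(u.index)
            # completeness: any pair is ordered at least one way
            for i, x in enumerate(ids):
                for y in ids[i + 1:]:
                    assert u[x] >= u[y] or u[y] >= u[x]
            # transitivity on a random triple chain
            rng = np.random.default_rng(9)
            for _ in range(20):
                x, y, z = rng.choice(ids, 3, replace=False)
                if u[x] >= u[y] and u[y] >= u[z]:
                    assert u[x] >= u[z]

    def test_tied_utilities_break_by_descending_id(self, params):
        cat = [ImpactVector(i, (1, -1, -1, -1, -1, -1)) for i in ("R1A1", "R2A1", "R9A3")]
        plan = rank_for_levels(_vec("c", [1.0, 3.0, 3.0, 3.0, 3.0, 3.0]), cat, params)
        assert plan.activity_order == ("R9A3", "R2A1", "R1A1")
        assert list(plan.table["rank"]) == [1, 2, 3]


def test_impact_vector_invariants():
    with pytest.raises(ValidationError):
        ImpactVector("A", (1, -1, -1, -1, -1))  # wrong length
    with pytest.raises(ValidationError):
        ImpactVector("A", (1, 0, -1, -1, -1, -1))  # not +/-1
    with pytest.raises(ValidationError):
        ImpactVector("A", (-1,) * 6)  # improves nothing


def test_utility_params_validation():
    with pytest.raises(ParameterError):
        UtilityParams(k_positive=0)
    with pytest.raises(ParameterError):
        UtilityParams(k_negative=-1)
    with pytest.raises(ParameterError):
        UtilityParams(neutral_threshold=3.5)
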