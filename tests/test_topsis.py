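"""TOPSIS ranking: step arithmetic, invariants, and the frozen case-study oracle."""

import numpy as np
import pytest

from reqrank import datasets
from reqrank.errors import CompletenessError, NumericError, ShapeError
from reqrank.survey_io import ScoreRecord, ScoreTable
from reqrank.topsis import (
    EvaluationMatrix,
    aggregate_scores,
    apply_weights,
    closeness,
    evaluate,
    ideal_solutions,
    rank_report,
    vector_normalize,
)

# Relative closeness of the bundled two-alternative case study (published
# evaluation matrix, renormalized published weight vector), computed once by
# an independent step-by-step script and frozen as the regression target.
FROZEN_CLOSENESS = {
    "design_scheme": 0.88175945610653,
    "evaluation_sample": 0.11824054389347,
}
FROZEN_S = {"design_scheme": (0.008782398878986, 0.065493298693063)}


def random_problem(rng, n_alt=None, n_ind=None):
    n_alt = n_alt or int(rng.integers(2, 6))
    n_ind = n_ind or int(rng.integers(2, 8))
    values = rng.uniform(1, 7, size=(n_alt, n_ind))
    m = EvaluationMatrix(
        alternatives=tuple(f"a{i}" for i in range(n_alt)),
        indicators=tuple(f"x{j}" for j in range(n_ind)),
        values=values,
    )
    w = rng.uniform(0.1, 1, size=n_ind)
    return m, w


class TestAggregate:
    def test_mean_of_two_raters(self):
        table = ScoreTable(
            [
                ScoreRecord("e1", "expert", "a", "x", 5),
                ScoreRecord("u1", "user", "a", "x", 6),
            ]
        )
        m = aggregate_scores(table)
        assert m.values[0, 0] == 5.5

    def test_unanimous_sevens(self):
        table = ScoreTable(
            [ScoreRecord(f"e{i}", "expert", "a", "x", 7) for i in range(5)]
        )
        assert aggregate_scores(table).values[0, 0] == 7.0

    def test_missing_cell_named(self):
        table = ScoreTable(
            [
                ScoreRecord("e1", "expert", "a", "x", 5),
                ScoreRecord("e1", "expert", "b", "y", 5),
            ]
        )
        with pytest.raises(CompletenessError, match="'a'"):
            aggregate_scores(table)


class TestSteps:
    def test_three_four_five_triangle(self):
        m = EvaluationMatrix(("a", "b"), ("x",), np.array([[3.0], [4.0]]))
        r = vector_normalize(m)
        assert np.allclose(r[:, 0], [0.6, 0.8])

    def test_single_alternative_normalizes_to_one(self):
        m = EvaluationMatrix(("a",), ("x",), np.array([[4.2]]))
        assert vector_normalize(m)[0, 0] == pytest.approx(1.0)

    def test_all_columns_unit_norm(self, rng):
        for _ in range(100):
            m, _ = random_problem(rng)
            r = vector_normalize(m)
            assert np.allclose(np.linalg.norm(r, axis=0), 1.0, atol=1e-12)

    def test_zero_column_rejected(self):
        m = EvaluationMatrix(("a", "b"), ("x",), np.array([[0.0], [0.0]]))
        with pytest.raises(NumericError):
            vector_normalize(m)

    def test_unit_weights_identity(self, rng):
        m, _ = random_problem(rng)
        r = vector_normalize(m)
        assert np.array_equal(apply_weights(r, np.ones(r.shape[1])), r)

    def test_zero_weight_zeroes_column(self, rng):
        m, w = random_problem(rng, n_ind=3)
        w = np.array([0.5, 0.0, 0.5])
        u = apply_weights(vector_normalize(m), w)
        assert np.all(u[:, 1] == 0)

    def test_weight_length_mismatch(self, rng):
        m, _ = random_problem(rng, n_ind=3)
        with pytest.raises(ShapeError):
            apply_weights(vector_normalize(m), [0.5, 0.5])

    def test_ideal_is_elementwise_max_for_benefit(self):
        u = np.array([[0.1, 0.5], [0.3, 0.2]])
        a_pos, a_neg = ideal_solutions(u, ["benefit", "benefit"])
        assert np.allclose(a_pos, [0.3, 0.5]) and np.allclose(a_neg, [0.1, 0.2])

    def test_cost_direction_swaps_ideals(self):
        u = np.array([[0.1, 0.5], [0.3, 0.2]])
        pb, nb = ideal_solutions(u, ["benefit", "benefit"])
        pc, nc = ideal_solutions(u, ["benefit", "cost"])
        assert pc[1] == nb[1] and nc[1] == pb[1]

    def test_single_alternative_ideals_coincide(self):
        u = np.array([[0.2, 0.3]])
        a_pos, a_neg = ideal_solutions(u, ["benefit", "benefit"])
        assert np.array_equal(a_pos, a_neg)


class TestCloseness:
    def test_dominance_extremes(self):
        m = EvaluationMatrix(
            ("worst", "best"), tuple("abc"), np.array([[1.0] * 3, [7.0] * 3])
        )
        res = evaluate(m, np.ones(3))
        assert res.closeness_by_alternative() == {"worst": 0.0, "best": 1.0}
        assert res.ranking == ("best", "worst")

    def test_two_alternative_identity(self, rng):
        for _ in range(100):
            m, w = random_problem(rng, n_alt=2)
            res = evaluate(m, w)
            assert res.closeness.sum() == pytest.approx(1.0, abs=1e-12)

    def test_published_closeness_pair_violates_identity(self):
        # the published pair 0.894 + 0.167 cannot arise from a
        # two-alternative all-benefit problem
        assert abs(0.894 + 0.167 - 1.0) > 0.05

    def test_weight_scale_invariance(self, rng):
        for _ in range(20):
            m, w = random_problem(rng)
            c1 = evaluate(m, w).closeness
            c2 = evaluate(m, w * 37.5).closeness
            assert np.allclose(c1, c2, atol=1e-12)

    def test_dominance_monotonicity(self, rng):
        for _ in range(50):
            m, w = random_problem(rng, n_alt=3)
            v = m.values.copy()
            v[0] = v[1] + rng.uniform(0.05, 0.3, size=v.shape[1])
            v = np.clip(v, 1, None)
            m2 = EvaluationMatrix(m.alternatives, m.indicators, v)
            res = evaluate(m2, w)
            c = res.closeness_by_alternative()
            assert c["a0"] > c["a1"]

    def test_identical_alternatives_flagged_at_half(self):
        m = EvaluationMatrix(("a", "b"), ("x", "y"), np.array([[3.0, 4.0], [3.0, 4.0]]))
        res = evaluate(m, [0.5, 0.5])
        assert np.all(res.closeness == 0.5)
        assert res.degenerate == ("a", "b")

    def test_permutation_equivariance(self, rng):
        m, w = random_problem(rng, n_alt=4, n_ind=5)
        res = evaluate(m, w)
        perm_a = [2, 0, 3, 1]
        perm_i = [4, 2, 0, 1, 3]
        m2 = EvaluationMatrix(
            tuple(m.alternatives[i] for i in perm_a),
            tuple(m.indicators[j] for j in perm_i),
            m.values[np.ix_(perm_a, perm_i)],
        )
        res2 = evaluate(m2, w[perm_i])
        for alt in m.alternatives:
            assert res.closeness_by_alternative()[alt] == pytest.approx(
                res2.closeness_by_alternative()[alt], abs=1e-12
            )


class TestCaseStudyOracle:
    def test_frozen_oracle_regression(self):
        res = evaluate(datasets.evaluation_matrix(), datasets.reported_weight_vector())
        for alt, expected in FROZEN_CLOSENESS.items():
            assert res.closeness_by_alternative()[alt] == pytest.approx(expected, abs=1e-9)
        i = res.alternatives.index("design_scheme")
        s_plus, s_minus = FROZEN_S["design_scheme"]
        assert res.s_plus[i] == pytest.approx(s_plus, abs=1e-9)
        assert res.s_minus[i] == pytest.approx(s_minus, abs=1e-9)


class TestRankReport:
    def test_rank_one_for_larger_closeness(self):
        res = evaluate(datasets.evaluation_matrix(), datasets.reported_weight_vector())
        table = rank_report(res)
        assert table.loc[table["alternative"] == "design_scheme", "rank"].item() == 1

    def test_tie_keeps_input_order_and_flags(self):
        m = EvaluationMatrix(("a", "b"), ("x", "y"), np.array([[3.0, 4.0], [3.0, 4.0]]))
        table = rank_report(evaluate(m, [0.5, 0.5]))
        assert list(table["rank"]) == [1, 2]
        assert table["tie"].all()
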