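"""AHP weighting: reciprocity handling, eigenvector recovery, consistency."""

import numpy as np
import pytest

from reqrank import datasets
from reqrank.ahp import (
    Hierarchy,
    PairwiseMatrix,
    WeightResult,
    consistency,
    load_random_index,
    priority_weights,
    repair_from_upper_triangle,
    synthesize_global,
    validate_reciprocity,
)
from reqrank.errors import ConfigurationError, IntegrityError
from reqrank.synthetic import MatrixPlantSpec, generate_pairwise_matrix


def consistent_matrix(w):
    w = np.asarray(w, dtype=float)
    return PairwiseMatrix(
        items=tuple(f"i{k}" for k in range(len(w))), values=np.outer(w, 1 / w)
    )


class TestReciprocity:
    def test_consistent_matrix_valid(self):
        assert validate_reciprocity(consistent_matrix([0.5, 0.3, 0.2])) == []

    def test_matrix_of_ones_valid(self):
        m = PairwiseMatrix(items=("a", "b"), values=np.ones((2, 2)))
        assert validate_reciprocity(m) == []

    def test_published_must_be_matrix_violations(self):
        # the printed 7×7 must-be matrix is not reciprocal, e.g. the
        # (M3, M4) judgment is 1 but its transpose is 2
        m = datasets.local_matrices()["M"]
        assert ("M3", "M4") in validate_reciprocity(m)

    def test_repair_produces_reciprocal_matrix(self):
        m = datasets.local_matrices()["M"]
        assert validate_reciprocity(repair_from_upper_triangle(m)) == []

    def test_repair_idempotent_on_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 7))
            v = np.exp(rng.normal(size=(n, n)))
            m = PairwiseMatrix(items=tuple(f"i{k}" for k in range(n)), values=v)
            once = repair_from_upper_triangle(m)
            twice = repair_from_upper_triangle(once)
            assert np.array_equal(once.values, twice.values)

    def test_already_reciprocal_unchanged(self):
        m = consistent_matrix([0.6, 0.3, 0.1])
        repaired = repair_from_upper_triangle(m)
        assert np.allclose(repaired.values, m.values, atol=1e-15)


class TestPriorityWeights:
    def test_consistent_limit_recovers_weights(self):
        res = priority_weights(consistent_matrix([0.5, 0.3, 0.2]))
        assert np.allclose(res.weights, [0.5, 0.3, 0.2], atol=1e-10)
        assert res.lambda_max == pytest.approx(3.0, abs=1e-9)
        assert res.ci == pytest.approx(0.0, abs=1e-9)
        assert res.cr == pytest.approx(0.0, abs=1e-9)

    def test_two_by_two_closed_form(self):
        m = PairwiseMatrix(items=("a", "b"), values=np.array([[1, 3], [1 / 3, 1]]))
        res = priority_weights(m)
        assert np.allclose(res.weights, [0.75, 0.25], atol=1e-10)
        assert res.lambda_max == pytest.approx(2.0, abs=1e-9)
        assert res.cr == 0.0

    def test_methods_agree_on_nearly_consistent_matrices(self, rng):
        checked = 0
        for seed in range(300):
            plant = MatrixPlantSpec(
                true_weights=(0.4, 0.25, 0.2, 0.15), sigma=0.03, seed=seed
            )
            m = generate_pairwise_matrix(plant)
            eig = priority_weights(m, "eigenvector")
            if eig.cr >= 0.1:
                continue
            gm = priority_weights(m, "geometric_mean")
            assert np.abs(eig.weights - gm.weights).sum() < 1e-3
            checked += 1
            if checked == 100:
                break
        assert checked == 100

    def test_strict_mode_rejects_nonreciprocal(self):
        m = datasets.local_matrices()["M"]
        with pytest.raises(IntegrityError):
            priority_weights(m, reciprocity="strict")
        # repair mode handles the same matrix
        res = priority_weights(m, reciprocity="repair_upper")
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_lambda_max_at_least_n_for_reciprocal(self, rng):
        for seed in range(50):
            m = generate_pairwise_matrix(
                MatrixPlantSpec(true_weights=(0.4, 0.3, 0.2, 0.1), sigma=0.4, seed=seed)
            )
            res = priority_weights(m)
            assert res.lambda_max >= 4 - 1e-9
            assert res.ci >= -1e-12

    def test_permutation_equivariance(self, rng):
        m = generate_pairwise_matrix(
            MatrixPlantSpec(true_weights=(0.4, 0.3, 0.2, 0.1), sigma=0.2, seed=3)
        )
        perm = [2, 0, 3, 1]
        pm = PairwiseMatrix(
            items=tuple(m.items[i] for i in perm),
            values=m.values[np.ix_(perm, perm)],
        )
        w = priority_weights(m).as_dict()
        wp = priority_weights(pm).as_dict()
        for k in w:
            assert w[k] == pytest.approx(wp[k], abs=1e-9)

    def test_recovery_error_monotone_in_sigma(self):
        true_w = (0.35, 0.25, 0.2, 0.12, 0.08)
        errors = []
        for sigma in (0.0, 0.05, 0.15, 0.4):
            errs = []
            for seed in range(200):
                m = generate_pairwise_matrix(
                    MatrixPlantSpec(true_weights=true_w, sigma=sigma, seed=seed)
                )
                res = priority_weights(m)
                errs.append(np.abs(res.weights - np.array(true_w)).sum())
            errors.append(np.mean(errs))
        assert errors[0] < 1e-10
        assert errors[0] < errors[1] < errors[2] < errors[3]


class TestConsistency:
    def test_published_one_dimensional_matrix_arithmetic(self):
        # λmax = 5.425 on a 5×5 matrix: CI = 0.10625 → 0.106, and with
        # RI(5) = 1.12, CR = 0.0949 → 0.095 (3 dp), as published
        ci, cr = consistency(5.425, 5)
        assert round(ci, 3) == 0.106
        assert round(cr, 3) == 0.095

    def test_published_attractive_matrix_arithmetic(self):
        ci, _ = consistency(5.441, 5)
        assert round(ci, 3) == 0.110

    def test_consistent_matrix_zero(self):
        assert consistency(5.0, 5) == (0.0, 0.0)

    def test_order_two_has_zero_cr(self):
        ci, cr = consistency(2.5, 2)
        assert cr == 0.0 and ci == pytest.approx(0.5)

    def test_missing_random_index_entry(self):
        with pytest.raises(ConfigurationError, match="n=15"):
            consistency(16.0, 15)

    def test_random_index_table_values(self):
        table = load_random_index()
        assert table[5] == 1.12 and table[8] == 1.41


class TestSynthesizeGlobal:
    @staticmethod
    def _wr(items, weights):
        return WeightResult(
            items=tuple(items),
            weights=np.asarray(weights, dtype=float),
            lambda_max=float(len(items)),
            ci=0.0,
            cr=0.0,
            ri_used=0.0,
            method="eigenvector",
        )

    def test_direct_product(self):
        crit = self._wr(("M", "O", "A"), (0.5, 0.3, 0.2))
        locals_ = {
            "M": self._wr(("m1", "m2"), (0.6, 0.4)),
            "O": self._wr(("o1",), (1.0,)),
            "A": self._wr(("a1", "a2"), (0.7, 0.3)),
        }
        h = synthesize_global(crit, locals_)
        expected = {"m1": 0.30, "m2": 0.20, "o1": 0.30, "a1": 0.14, "a2": 0.06}
        for k, v in expected.items():
            assert h.global_weights[k] == pytest.approx(v, abs=1e-12)
        assert sum(h.global_weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_category_equals_locals(self):
        crit = self._wr(("M",), (1.0,))
        locals_ = {"M": self._wr(("m1", "m2", "m3"), (0.5, 0.3, 0.2))}
        h = synthesize_global(crit, locals_)
        assert h.global_weights == pytest.approx({"m1": 0.5, "m2": 0.3, "m3": 0.2})

    def test_duplicate_indicator_rejected(self):
        crit = self._wr(("M", "O"), (0.5, 0.5))
        locals_ = {
            "M": self._wr(("x",), (1.0,)),
            "O": self._wr(("x",), (1.0,)),
        }
        with pytest.raises(IntegrityError):
            synthesize_global(crit, locals_)

    def test_published_layers_do_not_reproduce_published_combined_weights(self):
        # product-and-normalize on the repaired published matrices cannot
        # give the published combined column (0.3854 × 0.1560 ≠ 0.410)
        crit = priority_weights(datasets.criterion_matrix(), reciprocity="repair_upper")
        locals_ = {
            cat: priority_weights(m, reciprocity="repair_upper")
            for cat, m in datasets.local_matrices().items()
        }
        h = synthesize_global(crit, locals_)
        assert sum(h.global_weights.values()) == pytest.approx(1.0, abs=1e-9)
        reported = dict(
            zip(datasets.reported_weights()["indicator"], datasets.reported_weights()["combined_weight"])
        )
        assert abs(h.global_weights["M1"] - reported["M1"]) > 0.05

    def test_scale_relabeling_leaves_ranking_unchanged(self, rng):
        m = generate_pairwise_matrix(
            MatrixPlantSpec(true_weights=(0.4, 0.3, 0.2, 0.1), sigma=0.2, seed=8)
        )
        base = priority_weights(m)
        # consistent rescaling of row k and reciprocal column k relabels
        # the ratio scale; ranking must not change
        v = m.values.copy()
        k, c = 1, 2.0
        v[k, :] *= c
        v[:, k] /= c
        v[k, k] = 1.0
        rescaled = priority_weights(PairwiseMatrix(items=m.items, values=v))
        order = np.argsort(-base.weights)
        order_rescaled = np.argsort(-np.delete(rescaled.weights, k))
        base_wo_k = np.argsort(-np.delete(base.weights, k))
        assert np.array_equal(base_wo_k, order_rescaled)
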