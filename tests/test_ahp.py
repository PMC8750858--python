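"""Pairwise-comparison machinery: construction, eigenweights, consistency, repair."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given
from hypothesis import strategies as st

import autoahp as aa
from autoahp.ahp import SAATY_VALUES, AHPError, random_index


class TestSaatyScale:
    @pytest.mark.parametrize(
        "grade,value",
        [("equal", 1), ("moderate", 3), ("essential", 5), ("strong", 7), ("extreme", 9),
         ("intermediate_1", 2), ("intermediate_2", 4), ("intermediate_4", 8)],
    )
    def test_grades(self, grade, value):
        assert aa.saaty_value(grade) == value

    def test_intermediate_lies_between_odd_neighbours(self):
        v = aa.saaty_value("intermediate_2")
        assert aa.saaty_value("moderate") < v < aa.saaty_value("essential")

    def test_unknown_grade_rejected(self):
        with pytest.raises(AHPError, match="unknown importance grade"):
            aa.saaty_value("overwhelming")

    def test_quantize_nearest_in_log_space_brute_force(self):
        # exhaustive oracle over the 17-value scale
        rng = np.random.default_rng(42)
        for r in np.exp(rng.uniform(np.log(1 / 12), np.log(12), 200)):
            q = aa.quantize_ratio(r)
            dist = abs(np.log(r) - np.log(q))
            best = min(abs(np.log(r) - np.log(s)) for s in SAATY_VALUES)
            assert dist == pytest.approx(best, abs=1e-12)

    def test_quantize_tie_breaks_toward_one(self):
        # sqrt(2) is equidistant (log-space) between 1 and 2
        assert aa.quantize_ratio(np.sqrt(2.0)) == 1.0
        assert aa.quantize_ratio(1 / np.sqrt(2.0)) == 1.0


class TestMatrixFromWeights:
    def test_equal_weights_all_ones(self):
        A = aa.matrix_from_weights([1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(A.values, 1.0)

    def test_exact_ratios(self):
        A = aa.matrix_from_weights([0.6, 0.3, 0.1]).values
        assert A[0, 1] == pytest.approx(2.0)
        assert A[0, 2] == pytest.approx(6.0)
        assert A[1, 2] == pytest.approx(3.0)

    def test_quantized_matches_brute_force_oracle(self):
        w = np.array([0.55, 0.30, 0.15])
        A = aa.matrix_from_weights(w, quantize=True).values
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                r = w[i] / w[j]
                expected = min(SAATY_VALUES, key=lambda s: abs(np.log(r) - np.log(s)))
                assert A[i, j] == pytest.approx(expected)

    def test_zero_weights_floored(self):
        A = aa.matrix_from_weights([0.5, 0.5, 0.0])
        assert np.all(np.isfinite(A.values))

    @pytest.mark.parametrize("bad", [[1.0], [0.0, 0.0], [-0.1, 1.1]])
    def test_invalid_weights_rejected(self, bad):
        with pytest.raises(AHPError):
            aa.matrix_from_weights(bad)


class TestPairwiseMatrix:
    def test_reciprocity_enforced(self):
        with pytest.raises(AHPError, match="reciprocal"):
            aa.PairwiseMatrix([[1, 2], [2, 1]])

    def test_diagonal_enforced(self):
        with pytest.raises(AHPError, match="diagonal"):
            aa.PairwiseMatrix([[2, 1], [1, 1]])

    def test_order_bounds(self):
        with pytest.raises(AHPError):
            aa.PairwiseMatrix(np.eye(10) + np.ones((10, 10)) - np.eye(10))

    def test_csv_roundtrip(self, tmp_path, cyclic3):
        p = tmp_path / "m.csv"
        cyclic3.to_csv(p)
        back = aa.PairwiseMatrix.from_csv(p)
        assert np.allclose(back.values, cyclic3.values)


class TestPrincipalWeights:
    def test_consistent_matrix_recovers_weights_exactly(self):
        w = np.array([0.6, 0.3, 0.1])
        got, lam = aa.principal_weights(aa.matrix_from_weights(w))
        assert np.allclose(got, w, atol=1e-12)
        assert lam == pytest.approx(3.0, abs=1e-12)

    def test_any_2x2_is_consistent(self):
        for a in (2.0, 5.0, 1 / 7):
            _, lam = aa.principal_weights(aa.PairwiseMatrix([[1, a], [1 / a, 1]]))
            assert lam == pytest.approx(2.0, abs=1e-10)

    def test_cyclic_matches_dense_eigensolver(self, cyclic3):
        _, lam = aa.principal_weights(cyclic3)
        dense = max(scipy.linalg.eigvals(cyclic3.values).real)
        assert lam == pytest.approx(dense, abs=1e-9)

    @given(st.integers(0, 10_000))
    def test_recovery_property_random_weights(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        w = rng.dirichlet(np.ones(n))
        w = np.maximum(w, 1e-6)
        w /= w.sum()
        got, lam = aa.principal_weights(aa.matrix_from_weights(w))
        assert np.max(np.abs(got - w)) < 1e-9
        assert lam >= n - 1e-9

    def test_lambda_max_at_least_n_on_saaty_3x3_sample(self):
        # sampled from the exhaustively enumerable 17^3 grid
        rng = np.random.default_rng(3)
        for _ in range(300):
            a12, a13, a23 = rng.choice(SAATY_VALUES, 3)
            A = aa.PairwiseMatrix(
                [[1, a12, a13], [1 / a12, 1, a23], [1 / a13, 1 / a23, 1]]
            )
            _, lam = aa.principal_weights(A)
            consistent = np.isclose(a12 * a23, a13)
            assert lam >= 3 - 1e-9
            assert (lam <= 3 + 1e-9) == consistent


class TestLambdaMaxEstimate:
    def test_consistent_3x3(self):
        A = aa.matrix_from_weights([0.5, 0.25, 0.25])
        assert aa.lambda_max_estimate(A, [0.5, 0.25, 0.25]) == pytest.approx(3.0)

    def test_2x2(self):
        A = aa.PairwiseMatrix([[1, 3], [1 / 3, 1]])
        assert aa.lambda_max_estimate(A, [0.75, 0.25]) == pytest.approx(2.0)

    def test_agrees_with_eigensolver_on_cyclic(self, cyclic3):
        w, lam = aa.principal_weights(cyclic3)
        assert aa.lambda_max_estimate(cyclic3, w) == pytest.approx(lam, abs=1e-6)

    def test_zero_weight_rejected(self, cyclic3):
        with pytest.raises(AHPError):
            aa.lambda_max_estimate(cyclic3, [0.5, 0.5, 0.0])


class TestConsistency:
    def test_index_examples(self):
        assert aa.consistency_index(3.0, 3) == 0.0
        assert aa.consistency_index(2.0, 2) == 0.0
        with pytest.raises(AHPError):
            aa.consistency_index(3.0, 1)

    def test_index_of_cyclic_matches_eigensolver(self, cyclic3):
        dense = max(scipy.linalg.eigvals(cyclic3.values).real)
        assert aa.consistency_index(dense, 3) == pytest.approx((dense - 3) / 2)

    def test_ratio_examples(self):
        rep = aa.consistency_ratio(0.0, 5)
        assert rep.cr == 0.0 and rep.acceptable
        rep = aa.consistency_ratio(0.09 * random_index(4), 4)
        assert rep.cr == pytest.approx(0.09) and rep.acceptable
        with pytest.raises(AHPError):
            aa.consistency_ratio(0.1, 10)

    def test_order_two_always_acceptable(self):
        rep = aa.consistency_ratio(0.0, 2)
        assert rep.acceptable and rep.cr == 0.0

    def test_cyclic_unacceptable_with_standard_ri(self, cyclic3):
        rep = aa.consistency_report(cyclic3)
        assert rep.ri == 0.58
        assert rep.cr == pytest.approx(rep.ci / 0.58)
        assert not rep.acceptable


class TestRepair:
    def test_consistent_returned_unchanged(self):
        A = aa.matrix_from_weights([0.5, 0.3, 0.2])
        assert aa.repair_matrix(A) is A

    def test_order_two_identity_unchanged(self):
        A = aa.PairwiseMatrix([[1, 1], [1, 1]])
        assert aa.repair_matrix(A) is A

    def test_cyclic_repaired_below_threshold(self, cyclic3):
        fixed = aa.repair_matrix(cyclic3)
        rep = aa.consistency_report(fixed)
        assert rep.acceptable and rep.cr < 0.10
        assert fixed.is_saaty  # input was on the grid, output stays on it

    def test_repair_preserves_reciprocity(self, cyclic3):
        fixed = aa.repair_matrix(cyclic3).values
        assert np.allclose(fixed * fixed.T, 1.0)
        assert np.allclose(np.diag(fixed), 1.0)
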