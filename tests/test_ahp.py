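"""Crisp AHP: matrices, weights, consistency, group aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cszprio import (
    PairwiseComparisonMatrix,
    SAATY_RANDOM_INDEX,
    aggregate_group,
    consistency,
    eigenvector_weights,
    geometric_mean_weights,
    matrix_from_judgments,
)
from cszprio.ahp import eigen_lambda_max, read_matrix_csv, write_matrix_csv
from cszprio.fixtures import EXAMPLE_HAZARD_IDS, EXAMPLE_HAZARD_JUDGMENTS

ODD_SCALE = [1 / 9, 1 / 7, 1 / 5, 1 / 3, 1.0, 3.0, 5.0, 7.0, 9.0]


def consistent_matrix(weights, criteria=None, set_id="hazard"):
    w = np.asarray(weights, dtype=float)
    criteria = criteria or tuple(f"c{i}" for i in range(len(w)))
    return PairwiseComparisonMatrix(set_id, tuple(criteria), np.outer(w, 1.0 / w))


# strategy: small random reciprocal matrices with odd-scale upper triangles
@st.composite
def reciprocal_matrices(draw, max_order=5):
    n = draw(st.integers(min_value=2, max_value=max_order))
    a = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x = draw(st.sampled_from(ODD_SCALE))
            a[i, j] = x
            a[j, i] = 1.0 / x
    return PairwiseComparisonMatrix("hazard", tuple(f"c{i}" for i in range(n)), a)


class TestMatrixConstruction:
    def test_single_judgment_forces_reciprocity(self):
        m = matrix_from_judgments([("A", "B", 3.0)], ("A", "B"))
        assert np.allclose(m.values, [[1, 3], [1 / 3, 1]])

    def test_fixture_matrix_layout(self, hazard_matrix):
        assert hazard_matrix.criteria == EXAMPLE_HAZARD_IDS
        assert hazard_matrix.order == 4
        # flooding row dominates
        assert hazard_matrix.values[1, 0] == 7.0
        assert hazard_matrix.values[0, 1] == pytest.approx(1 / 7)

    def test_missing_pair_is_named(self):
        with pytest.raises(ValueError, match="'A'.*'C'"):
            matrix_from_judgments([("A", "B", 3.0)], ("A", "B", "C"))

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            matrix_from_judgments([("A", "B", 3.0), ("B", "A", 5.0)], ("A", "B"))

    def test_non_positive_intensity_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            matrix_from_judgments([("A", "B", 0.0)], ("A", "B"))

    def test_non_reciprocal_values_rejected(self):
        with pytest.raises(ValueError, match="reciprocal"):
            PairwiseComparisonMatrix("hazard", ("a", "b"), np.array([[1.0, 2.0], [1.0, 1.0]]))


class TestWeights:
    def test_identity_gives_equal_weights(self):
        m = PairwiseComparisonMatrix("hazard", ("a", "b", "c"), np.ones((3, 3)))
        assert np.allclose(geometric_mean_weights(m).weights, 1 / 3)
        assert np.allclose(eigenvector_weights(m).weights, 1 / 3)

    def test_two_by_two_closed_form(self):
        m = matrix_from_judgments([("A", "B", 3.0)], ("A", "B"))
        assert np.allclose(geometric_mean_weights(m).weights, [0.75, 0.25])

    def test_fixture_reproduces_published_weights(self, hazard_matrix):
        w = geometric_mean_weights(hazard_matrix)
        assert np.allclose(w.weights, [0.1010, 0.6502, 0.1904, 0.0583], atol=1e-4)
        assert [round(x, 2) for x in w.weights] == [0.10, 0.65, 0.19, 0.06]

    @pytest.mark.parametrize("weights", [(0.5, 0.3, 0.2), (0.7, 0.1, 0.1, 0.1)])
    def test_both_methods_exact_on_consistent_matrices(self, weights):
        m = consistent_matrix(weights)
        assert np.allclose(geometric_mean_weights(m).weights, weights, atol=1e-12)
        assert np.allclose(eigenvector_weights(m).weights, weights, atol=1e-9)

    def test_methods_agree_on_fixture_within_tolerance(self, hazard_matrix):
        gm = geometric_mean_weights(hazard_matrix).weights
        ev = eigenvector_weights(hazard_matrix, tolerance=1e-12).weights
        assert np.max(np.abs(gm - ev)) < 0.01

    def test_eigenvector_matches_dense_eigen_oracle(self, hazard_matrix):
        # independent LAPACK route
        vals, vecs = np.linalg.eig(hazard_matrix.values)
        principal = np.real(vecs[:, np.argmax(vals.real)])
        principal = np.abs(principal) / np.abs(principal).sum()
        assert np.allclose(eigenvector_weights(hazard_matrix).weights, principal, atol=1e-9)


class TestConsistency:
    @pytest.mark.parametrize("n", sorted(SAATY_RANDOM_INDEX))
    def test_identity_is_perfectly_consistent_at_every_order(self, n):
        m = PairwiseComparisonMatrix("hazard", tuple(f"c{i}" for i in range(n)), np.ones((n, n)))
        report = consistency(m)
        assert report.cr == 0.0
        assert report.acceptable

    def test_any_2x2_has_zero_ci(self):
        m = matrix_from_judgments([("A", "B", 9.0)], ("A", "B"))
        report = consistency(m)
        assert report.ci == 0.0 and report.cr == 0.0

    def test_fixture_passes_gate(self, hazard_matrix):
        report = consistency(hazard_matrix, geometric_mean_weights(hazard_matrix))
        assert report.lambda_max == pytest.approx(4.2278, abs=1e-3)
        assert report.cr == pytest.approx(0.084, abs=2e-3)
        assert report.acceptable

    def test_row_ratio_lambda_max_close_to_eigen_oracle(self, hazard_matrix):
        report = consistency(hazard_matrix)
        assert report.lambda_max == pytest.approx(eigen_lambda_max(hazard_matrix), abs=5e-3)

    def test_three_cycle_fails_gate(self):
        m = matrix_from_judgments(
            [("A", "B", 3.0), ("B", "C", 3.0), ("C", "A", 3.0)], ("A", "B", "C")
        )
        assert not consistency(m).acceptable

    def test_order_beyond_ri_table_rejected(self):
        n = max(SAATY_RANDOM_INDEX) + 1
        m = PairwiseComparisonMatrix("hazard", tuple(f"c{i}" for i in range(n)), np.ones((n, n)))
        with pytest.raises(ValueError, match="random index"):
            consistency(m)


class TestGroupAggregation:
    def test_identical_matrices_unchanged(self, hazard_matrix):
        agg = aggregate_group([hazard_matrix, hazard_matrix])
        assert np.allclose(agg.values, hazard_matrix.values)

    def test_opposing_judgments_cancel(self):
        m1 = matrix_from_judgments([("A", "B", 3.0)], ("A", "B"))
        m2 = matrix_from_judgments([("A", "B", 1 / 3)], ("A", "B"))
        assert np.allclose(aggregate_group([m1, m2]).values, 1.0)

    def test_group_of_consistent_matrices_is_consistent_with_gm_weights(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(2, 6)
            k = rng.integers(1, 5)
            ws = rng.dirichlet(np.ones(n), size=k)
            agg = aggregate_group([consistent_matrix(w) for w in ws])
            assert agg.is_consistent(tol=1e-9)
            gm_of_weights = np.exp(np.mean(np.log(ws), axis=0))
            gm_of_weights /= gm_of_weights.sum()
            assert np.allclose(geometric_mean_weights(agg).weights, gm_of_weights, atol=1e-12)

    def test_mismatched_sets_rejected(self, hazard_matrix):
        other = PairwiseComparisonMatrix("transmission", ("a", "b"), np.ones((2, 2)))
        with pytest.raises(ValueError, match="mixed|ordering"):
            aggregate_group([hazard_matrix, other])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_group([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(matrices=st.lists(reciprocal_matrices(max_order=3), min_size=1, max_size=4))
    def test_reciprocity_preserved(self, matrices):
        # restrict to a common order so aggregation applies
        n = matrices[0].order
        same = [m for m in matrices if m.order == n]
        agg = aggregate_group(same)
        assert np.allclose(agg.values * agg.values.T, 1.0, atol=1e-12)
        assert np.allclose(np.diag(agg.values), 1.0)


class TestMatrixCSV:
    def test_round_trip_preserves_fractions(self, tmp_path, hazard_matrix):
        path = tmp_path / "matrix.csv"
        write_matrix_csv(hazard_matrix, path)
        text = path.read_text()
        assert "1/7" in text and "1/3" in text
        reloaded = read_matrix_csv(path, set_id="hazard")
        assert reloaded.criteria == hazard_matrix.criteria
        assert np.allclose(reloaded.values, hazard_matrix.values)
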