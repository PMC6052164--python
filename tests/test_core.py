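import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nnclust.core import (
    Assignment,
    DataMatrix,
    cluster_means,
    normalize_matrix,
    nuclear_norm,
    objective,
    pooled_residual,
    singular_spectrum,
)

finite_matrices = arrays(
    np.float64,
    shape=st.tuples(st.integers(1, 12), st.integers(1, 12)),
    elements=st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False),
)


class TestNormalizeMatrix:
    def test_zscore_simple_column(self):
        M = normalize_matrix(np.array([[1.0], [2.0], [3.0]]), method="zscore")
        np.testing.assert_allclose(M.values[:, 0], [-1.0, 0.0, 1.0])

    def test_zscore_columns_standardized(self, rng):
        M = normalize_matrix(rng.normal(5, 3, size=(40, 6)), method="zscore")
        np.testing.assert_allclose(M.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(M.values.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_minmax_range(self, rng):
        M = normalize_matrix(rng.normal(size=(30, 4)), method="minmax")
        np.testing.assert_allclose(M.values.min(axis=0), 0.0, atol=1e-15)
        np.testing.assert_allclose(M.values.max(axis=0), 1.0, atol=1e-15)

    def test_none_is_identity(self, rng):
        raw = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(normalize_matrix(raw, method="none").values, raw)

    @pytest.mark.parametrize("method", ["zscore", "minmax"])
    def test_constant_column_warns_and_zeroes(self, method):
        raw = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        with pytest.warns(UserWarning, match="constant"):
            M = normalize_matrix(raw, method=method)
        np.testing.assert_array_equal(M.values[:, 0], 0.0)

    def test_non_finite_cell_named(self):
        raw = np.array([[1.0, 2.0], [np.nan, 4.0]])
        with pytest.raises(ValueError, match="row 1, column 0"):
            normalize_matrix(raw)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown normalization"):
            normalize_matrix(np.ones((2, 2)), method="bogus")


class TestClusterMeans:
    def test_single_cluster(self):
        M = DataMatrix(np.array([[0.0, 0.0], [2.0, 2.0]]))
        means = cluster_means(M, Assignment(labels=np.array([0, 0]), K=1))
        np.testing.assert_array_equal(means.centers, [[1.0, 1.0]])
        np.testing.assert_array_equal(means.counts, [2])

    def test_two_clusters(self, small_matrix, small_assignment):
        means = cluster_means(small_matrix, small_assignment)
        np.testing.assert_array_equal(means.centers, [[2.0, 0.0], [5.0, 10.0]])
        np.testing.assert_array_equal(means.counts, [2, 1])

    def test_empty_cluster_placeholder(self):
        M = DataMatrix(np.array([[1.0, 1.0]]))
        means = cluster_means(M, Assignment(labels=np.array([0]), K=2))
        np.testing.assert_array_equal(means.counts, [1, 0])
        np.testing.assert_array_equal(means.centers[1], [0.0, 0.0])

    def test_counts_sum_to_n(self, rng):
        M = DataMatrix(rng.normal(size=(23, 3)))
        A = Assignment(labels=rng.integers(0, 4, size=23), K=4)
        assert cluster_means(M, A).counts.sum() == 23


class TestPooledResidual:
    def test_grand_mean_at_origin(self):
        M = DataMatrix(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        R = pooled_residual(M, Assignment(labels=np.array([0, 0]), K=1))
        np.testing.assert_allclose(R, [[1.0, 0.0], [-1.0, 0.0]])

    def test_identical_rows_give_zero(self):
        M = DataMatrix(np.array([[2.0, 3.0], [2.0, 3.0], [7.0, 7.0]]))
        R = pooled_residual(M, Assignment(labels=np.array([0, 0, 1]), K=2))
        np.testing.assert_allclose(R, 0.0, atol=1e-14)

    def test_worked_example(self, small_matrix, small_assignment):
        R = pooled_residual(small_matrix, small_assignment)
        np.testing.assert_allclose(R, [[-1.0, 0.0], [1.0, 0.0], [0.0, 0.0]])

    def test_within_cluster_rows_sum_to_zero(self, rng):
        M = DataMatrix(rng.normal(size=(30, 5)))
        A = Assignment(labels=rng.integers(0, 3, size=30), K=3)
        R = pooled_residual(M, A)
        for k in range(3):
            np.testing.assert_allclose(R[A.labels == k].sum(axis=0), 0.0, atol=1e-10)


class TestNuclearNorm:
    def test_zero_matrix(self):
        assert nuclear_norm(np.zeros((3, 3))) == 0.0

    def test_diagonal(self):
        assert nuclear_norm(np.diag([3.0, 4.0])) == pytest.approx(7.0)

    def test_rank_one_ones(self):
        # eigenvalues of X^T X = [[2,2],[2,2]] are 4 and 0 -> sum of sqrts = 2
        assert nuclear_norm(np.ones((2, 2))) == pytest.approx(2.0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            nuclear_norm(np.array([[1.0, np.inf]]))

    @settings(max_examples=100, deadline=None)
    @given(finite_matrices)
    def test_gram_eigenvalue_oracle(self, X):
        # independent path: sum of sqrt of eigenvalues of the (smaller) Gram
        # matrix, which shares the nonzero spectrum of X^T X
        n, p = X.shape
        gram = X @ X.T if n <= p else X.T @ X
        lam = np.linalg.eigvalsh(gram)
        expected = np.sqrt(np.clip(lam, 0.0, None)).sum()
        # rank-deficient inputs: each zero eigenvalue of the Gram matrix is
        # computed only to ~eps*lam_max, contributing sqrt of that after the
        # square root -- an error of the oracle path itself, not of the SVD
        oracle_err = min(n, p) * np.sqrt(np.finfo(float).eps * max(lam.max(), 0.0))
        assert nuclear_norm(X) == pytest.approx(expected, rel=1e-8, abs=1e-8 + oracle_err)

    @settings(max_examples=50, deadline=None)
    @given(finite_matrices)
    def test_unitary_invariance(self, X):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(X.shape[1],) * 2))
        assert nuclear_norm(X @ q) == pytest.approx(nuclear_norm(X), rel=1e-8, abs=1e-8)

    @settings(max_examples=50, deadline=None)
    @given(finite_matrices, st.floats(-10, 10, allow_nan=False))
    def test_absolute_homogeneity(self, X, c):
        assert nuclear_norm(c * X) == pytest.approx(abs(c) * nuclear_norm(X), rel=1e-8, abs=1e-8)

    def test_spectrum_sorted_and_sums(self, rng):
        X = rng.normal(size=(8, 5))
        s = singular_spectrum(X)
        assert np.all(s >= 0)
        assert np.all(np.diff(s) <= 0)
        assert s.sum() == pytest.approx(nuclear_norm(X))


class TestObjective:
    def test_identical_rows_per_cluster_zero(self):
        M = DataMatrix(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0], [5.0, 5.0]]))
        A = Assignment(labels=np.array([0, 0, 1, 1]), K=2)
        assert objective(A, M) == pytest.approx(0.0, abs=1e-10)

    def test_single_cluster_worked_value(self):
        M = DataMatrix(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        A = Assignment(labels=np.array([0, 0]), K=1)
        assert objective(A, M) == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_nonnegative(self, rng):
        M = DataMatrix(rng.normal(size=(12, 4)))
        A = Assignment(labels=rng.integers(0, 3, size=12), K=3)
        assert objective(A, M) >= 0

    def test_label_permutation_invariance(self, rng):
        M = DataMatrix(rng.normal(size=(15, 4)))
        labels = rng.integers(0, 3, size=15)
        perm = np.array([2, 0, 1])
        a = objective(Assignment(labels=labels, K=3), M)
        b = objective(Assignment(labels=perm[labels], K=3), M)
        assert a == pytest.approx(b, rel=1e-12)

    def test_row_permutation_equivariance(self, rng):
        M = rng.normal(size=(15, 4))
        labels = rng.integers(0, 3, size=15)
        order = rng.permutation(15)
        a = objective(Assignment(labels=labels, K=3), DataMatrix(M))
        b = objective(Assignment(labels=labels[order], K=3), DataMatrix(M[order]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_law(self, rng):
        M = DataMatrix(rng.normal(size=(10, 3)))
        A = Assignment(labels=rng.integers(0, 2, size=10), K=2)
        R = pooled_residual(M, A)
        assert (objective(A, M) < 1e-10) == np.allclose(R, 0.0, atol=1e-10)


class TestValidation:
    def test_assignment_label_range(self):
        with pytest.raises(ValueError):
            Assignment(labels=np.array([0, 2]), K=2)

    def test_assignment_length_mismatch(self, small_matrix):
        A = Assignment(labels=np.array([0, 1]), K=2)
        with pytest.raises(ValueError, match="length"):
            A.validate_for(small_matrix)

    def test_data_matrix_rejects_nan(self):
        with pytest.raises(ValueError):
            DataMatrix(np.array([[1.0, np.nan]]))

    def test_data_matrix_rejects_empty(self):
        with pytest.raises(ValueError):
            DataMatrix(np.empty((0, 3)))
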