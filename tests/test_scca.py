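"""Sparse-CCA core: soft thresholding, PMD, unpenalized CCA, deflation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import linalg

from envlink import (
    canonical_correlation,
    cca_unpenalized,
    pmd_rank1,
    projection_deflate,
    soft_threshold,
)


def brute_force_cca(X, Y):
    """Generalized-eigenvalue oracle for the first canonical pair."""
    n = X.shape[0]
    Xc, Yc = X - X.mean(0), Y - Y.mean(0)
    Sxx, Syy = Xc.T @ Xc / (n - 1), Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    A = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    evals, evecs = linalg.eig(A)
    k = np.argmax(evals.real)
    w_x = evecs[:, k].real
    w_y = np.linalg.solve(Syy, Sxy.T @ w_x)
    r = np.sqrt(max(evals[k].real, 0.0))
    return w_x / np.linalg.norm(w_x), w_y / np.linalg.norm(w_y), min(r, 1.0)


class TestSoftThreshold:
    def test_zero_lambda_identity(self, rng):
        v = rng.standard_normal(10)
        assert np.array_equal(soft_threshold(v, 0.0), v)

    def test_direct_formula(self):
        out = soft_threshold(np.array([3.0, -1.0, 0.5]), 1.0)
        assert np.allclose(out, [2.0, 0.0, 0.0])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30), st.data())
    def test_l1_norm_nonincreasing_in_lambda(self, vals, data):
        v = np.asarray(vals)
        lam1 = data.draw(st.floats(0, 50))
        lam2 = data.draw(st.floats(0, 50))
        lo, hi = sorted([lam1, lam2])
        assert np.abs(soft_threshold(v, hi)).sum() <= np.abs(soft_threshold(v, lo)).sum() + 1e-9


class TestPmdRank1:
    def test_full_sparsity_equals_svd(self, rng):
        X = rng.standard_normal((400, 12))
        Y = rng.standard_normal((400, 8))
        C = (X - X.mean(0)).T @ (Y - Y.mean(0)) / 399
        U, _, Vt = linalg.svd(C, full_matrices=False)
        sw = pmd_rank1(X - X.mean(0), Y - Y.mean(0), 1.0, 1.0)
        assert min(np.abs(sw.w_x - U[:, 0]).max(), np.abs(sw.w_x + U[:, 0]).max()) < 1e-6
        assert min(np.abs(sw.w_y - Vt[0]).max(), np.abs(sw.w_y + Vt[0]).max()) < 1e-6

    def test_identical_strong_column_dominates(self, rng):
        z = rng.standard_normal(1000)
        X = np.column_stack([z, rng.standard_normal((1000, 4))])
        Y = np.column_stack([z, rng.standard_normal((1000, 4))])
        sw = pmd_rank1(X, Y, 0.5, 0.5)
        assert abs(sw.w_x[0]) > 0.99 and abs(sw.w_y[0]) > 0.99
        assert canonical_correlation(X, Y, sw.w_x, sw.w_y) > 0.99

    def test_sparse_support_recovery(self, rng):
        n, p, k = 5000, 50, 5
        f = rng.standard_normal(n)
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, p))
        X[:, :k] = 2 * f[:, None] + rng.standard_normal((n, k))
        Y[:, :k] = 2 * f[:, None] + rng.standard_normal((n, k))
        sw = pmd_rank1(X - X.mean(0), Y - Y.mean(0), 0.5, 0.5)
        recall = np.count_nonzero(sw.w_x[:k]) / k
        assert recall >= 0.8

    def test_objective_monotone_nondecreasing(self, rng):
        X = rng.standard_normal((300, 20))
        Y = rng.standard_normal((300, 15))
        sw = pmd_rank1(X, Y, 0.4, 0.4)
        hist = np.asarray(sw.objective_history)
        assert np.all(np.diff(hist) >= -1e-10)

    def test_l1_bound_respected(self, rng):
        X = rng.standard_normal((200, 30))
        Y = rng.standard_normal((200, 10))
        sw = pmd_rank1(X, Y, 0.5, 0.5)
        assert np.abs(sw.w_x).sum() <= 0.5 * np.sqrt(30) + 1e-6
        assert np.linalg.norm(sw.w_x) == pytest.approx(1.0, abs=1e-9)

    def test_zero_covariance_rejected(self):
        X = np.zeros((50, 3))
        Y = np.zeros((50, 2))
        with pytest.raises(ValueError, match="no covariance signal"):
            pmd_rank1(X, Y, 1.0, 1.0)


class TestUnpenalizedCca:
    def test_identical_views_perfect_correlation(self, rng):
        X = rng.standard_normal((200, 5))
        fit = cca_unpenalized(X, X.copy(), ridge_eps=0.0)
        assert fit.canonical_r == pytest.approx(1.0, abs=1e-10)

    def test_bivariate_reduces_to_pearson(self, rng):
        x = rng.standard_normal((300, 1))
        y = 0.6 * x + 0.8 * rng.standard_normal((300, 1))
        fit = cca_unpenalized(x, y, ridge_eps=0.0)
        assert fit.canonical_r == pytest.approx(abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1]), abs=1e-10)

    def test_matches_generalized_eigen_oracle(self, rng):
        X = rng.standard_normal((500, 6))
        Y = rng.standard_normal((500, 4))
        fit = cca_unpenalized(X, Y, ridge_eps=0.0)
        wx, wy, r = brute_force_cca(X, Y)
        assert fit.canonical_r == pytest.approx(r, abs=1e-8)
        assert min(np.abs(fit.w_x - wx).max(), np.abs(fit.w_x + wx).max()) < 1e-8

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError, match="stability selection"):
            cca_unpenalized(rng.standard_normal((5, 10)), rng.standard_normal((5, 2)))


class TestDeflation:
    def test_projector_annihilates_direction(self, rng):
        M = rng.standard_normal((100, 8))
        w = rng.standard_normal(8)
        w /= np.linalg.norm(w)
        assert np.abs(projection_deflate(M, w) @ w).max() < 1e-12

    def test_basis_vector_zeroes_single_column(self, rng):
        M = rng.standard_normal((50, 4))
        e1 = np.array([1.0, 0, 0, 0])
        out = projection_deflate(M, e1)
        assert np.all(out[:, 0] == 0) and np.array_equal(out[:, 1:], M[:, 1:])

    def test_idempotent(self, rng):
        M = rng.standard_normal((60, 6))
        w = rng.standard_normal(6)
        w /= np.linalg.norm(w)
        once = projection_deflate(M, w)
        assert np.allclose(projection_deflate(once, w), once, atol=1e-12)

    def test_non_unit_weight_rejected(self, rng):
        with pytest.raises(ValueError, match="unit"):
            projection_deflate(rng.standard_normal((10, 3)), np.array([1.0, 1.0, 0.0]))


class TestCanonicalCorrelation:
    def test_consistent_with_fit(self, rng):
        X = rng.standard_normal((400, 5))
        Y = 0.5 * X[:, :3] + rng.standard_normal((400, 3))
        fit = cca_unpenalized(X, Y, ridge_eps=0.0)
        r = canonical_correlation(X - X.mean(0), Y - Y.mean(0), fit.w_x, fit.w_y)
        assert r == pytest.approx(fit.canonical_r, abs=1e-10)

    def test_null_views_near_zero(self, rng):
        X = rng.standard_normal((10000, 6))
        Y = rng.standard_normal((10000, 6))
        w = np.ones(6) / np.sqrt(6)
        assert abs(canonical_correlation(X, Y, w, w)) < 0.05

    def test_sign_flip_antisymmetry(self, rng):
        X = rng.standard_normal((100, 3))
        Y = rng.standard_normal((100, 3))
        w = np.array([1.0, 0, 0])
        r = canonical_correlation(X, Y, w, w)
        assert canonical_correlation(X, Y, -w, w) == pytest.approx(-r, abs=1e-12)

    def test_zero_variance_variate_rejected(self):
        X = np.ones((50, 2))
        Y = np.random.default_rng(0).standard_normal((50, 2))
        with pytest.raises(ValueError, match="zero-variance"):
            canonical_correlation(X, Y, np.array([1.0, 0]), np.array([1.0, 0]))
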