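"""Rank-one sparse CCA core: penalized matrix decomposition and deflation.

The sparse step solves max w_x' C w_y subject to ||w||_2 = 1 and
||w||_1 <= s * sqrt(p) per view (C the cross-covariance), by alternating
soft-thresholded power iterations -- the classic penalized matrix
decomposition. The unpenalized refit computes the leading canonical pair on
the selected columns by whitened SVD, and successive modes are obtained by
projection deflation M(I - ww').
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "SparseWeights",
    "CcaFit",
    "soft_threshold",
    "pmd_rank1",
    "cca_unpenalized",
    "projection_deflate",
    "canonical_correlation",
]


@dataclass
class SparseWeights:
    w_x: np.ndarray
    w_y: np.ndarray
    sparsity_x: float
    sparsity_y: float
    iterations: int
    converged: bool
    objective: float = 0.0
    objective_history: list = None


@dataclass
class CcaFit:
    w_x: np.ndarray
    w_y: np.ndarray
    canonical_r: float
    ridge_eps: float


def soft_threshold(v: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise sign(v) * max(|v| - lam, 0)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def _sparse_unit(v: np.ndarray, c: float) -> np.ndarray:
    """L2-normalized soft-thresholded v with ||.||_1 <= c.

    The threshold is the smallest lam for which the L1 norm of the
    normalized soft-thresholded vector meets the bound (lam = 0 when the
    bound already holds). The L1/L2 ratio of soft_threshold(v, lam) is
    piecewise-smooth and strictly decreasing in lam, so the crossing point
    solves a per-segment quadratic over the sorted |v| -- an exact O(p log p)
    computation.
    """
    absv = np.abs(v)
    nrm = np.sqrt(v @ v)
    if nrm == 0:
        return v
    l1_total = absv.sum()
    if l1_total <= c * nrm:
        return v / nrm
    if c <= 1.0:  # the bound forces a single coordinate
        w = np.zeros_like(v)
        j = int(absv.argmax())
        w[j] = np.sign(v[j])
        return w
    a = np.sort(absv)[::-1]
    cum1 = np.cumsum(a)
    cum2 = np.cumsum(a * a)
    p = len(a)
    k_arr = np.arange(1, p + 1)
    # ratio at the low-lam end of each segment (lam = a_{k+1}, with a_{p+1}=0)
    nxt = np.empty(p)
    nxt[:-1] = a[1:]
    nxt[-1] = 0.0
    l1 = cum1 - k_arr * nxt
    l2sq = cum2 - 2 * nxt * cum1 + k_arr * nxt * nxt
    np.maximum(l2sq, 1e-300, out=l2sq)
    ratio = l1 / np.sqrt(l2sq)
    k = int(np.searchsorted(ratio, c)) + 1  # ratio is non-decreasing in k
    if k > p:
        k = p
    s1, s2 = cum1[k - 1], cum2[k - 1]
    A = k * (k - c**2)
    B = -2 * s1 * (k - c**2)
    Cq = s1 * s1 - c**2 * s2
    if abs(A) < 1e-30:
        lam = -Cq / B if B != 0 else 0.0
    else:
        disc = max(B * B - 4 * A * Cq, 0.0)
        sq = np.sqrt(disc)
        r1, r2 = (-B - sq) / (2 * A), (-B + sq) / (2 * A)
        lo, hi = nxt[k - 1], a[k - 1]
        if lo - 1e-12 <= r1 <= hi + 1e-12:
            lam = r1
        elif lo - 1e-12 <= r2 <= hi + 1e-12:
            lam = r2
        else:
            lam = min(max(r1, lo), hi)
    if lam < 0:
        lam = 0.0
    su = np.sign(v) * np.maximum(absv - lam, 0.0)
    nrm = np.sqrt(su @ su)
    if nrm == 0:  # numerical corner: fall back to the top coordinate
        w = np.zeros_like(v)
        j = int(absv.argmax())
        w[j] = np.sign(v[j])
        return w
    return su / nrm


def pmd_rank1(
    X: np.ndarray,
    Y: np.ndarray,
    s_x: float = 0.5,
    s_y: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 100,
    init: np.ndarray | None = None,
) -> SparseWeights:
    """Rank-one penalized matrix decomposition of the cross-covariance.

    ``s_x``/``s_y`` in [1/sqrt(p), 1] set the L1 bound c = s * sqrt(p); s=1
    recovers the unconstrained leading singular pair of C = X'Y/(n-1).
    Initialization defaults to the leading singular vectors of C, making the
    fit deterministic.
    """
    n = X.shape[0]
    C = X.T @ Y / (n - 1)
    if not np.any(C):
        raise ValueError("no covariance signal: cross-covariance is identically zero")
    p, q = C.shape
    c_x, c_y = s_x * np.sqrt(p), s_y * np.sqrt(q)
    if init is None:
        _, _, Vt = np.linalg.svd(C, full_matrices=False)
        w_y = Vt[0]
    else:
        w_y = np.asarray(init, dtype=float)
        w_y = w_y / np.linalg.norm(w_y)
    w_x = np.zeros(p)
    converged = False
    it = 0
    history = []
    for it in range(1, max_iter + 1):
        w_x_new = _sparse_unit(C @ w_y, c_x)
        w_y_new = _sparse_unit(C.T @ w_x_new, c_y)
        delta = max(np.abs(w_x_new - w_x).max(), np.abs(w_y_new - w_y).max())
        w_x, w_y = w_x_new, w_y_new
        history.append(abs(float(w_x @ C @ w_y)))
        if delta < tol:
            converged = True
            break
    obj = float(w_x @ C @ w_y)
    if obj < 0:  # sign convention: canonical correlation >= 0
        w_y = -w_y
        obj = -obj
    return SparseWeights(w_x, w_y, s_x, s_y, it, converged, objective=obj, objective_history=history)


def _inv_sqrt(S: np.ndarray, eps: float) -> np.ndarray:
    evals, evecs = linalg.eigh(S + eps * np.eye(S.shape[0]))
    evals = np.maximum(evals, np.finfo(float).tiny)
    return evecs @ np.diag(evals**-0.5) @ evecs.T


def cca_unpenalized(X: np.ndarray, Y: np.ndarray, ridge_eps: float = 1e-6) -> CcaFit:
    """First canonical pair via SVD of the whitened cross-covariance.

    A small ridge eps stabilizes whitening on near-collinear stable sets.
    The leading singular value (clipped to [0, 1]) is the canonical r; the
    back-transformed weights are unit-normalized with the sign fixed so the
    sample canonical correlation is non-negative.
    """
    n = X.shape[0]
    if n < X.shape[1] or n < Y.shape[1]:
        raise ValueError("fewer rows than columns; apply stability selection first")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    Kx = _inv_sqrt(Sxx, ridge_eps)
    Ky = _inv_sqrt(Syy, ridge_eps)
    U, svals, Vt = linalg.svd(Kx @ Sxy @ Ky, full_matrices=False)
    r = float(np.clip(svals[0], 0.0, 1.0))
    w_x = Kx @ U[:, 0]
    w_y = Ky @ Vt[0]
    w_x /= np.linalg.norm(w_x)
    w_y /= np.linalg.norm(w_y)
    if np.corrcoef(Xc @ w_x, Yc @ w_y)[0, 1] < 0:
        w_y = -w_y
    return CcaFit(w_x, w_y, r, ridge_eps)


def projection_deflate(M: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Project the columns of M onto the orthogonal complement of w.

    Returns M' = M (I - w w'); exactly M' w = 0.
    """
    w = np.asarray(w, dtype=float)
    if abs(np.linalg.norm(w) - 1.0) > 1e-8:
        raise ValueError("deflation weight must have unit Euclidean norm")
    return M - np.outer(M @ w, w)


def canonical_correlation(X: np.ndarray, Y: np.ndarray, w_x: np.ndarray, w_y: np.ndarray) -> float:
    """Pearson correlation of the variates X w_x and Y w_y."""
    u = X @ w_x
    v = Y @ w_y
    if u.std() == 0 or v.std() == 0:
        raise ValueError("zero-variance canonical variate")
    return float(np.corrcoef(u, v)[0, 1])
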