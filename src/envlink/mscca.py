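"""Three-block sparse CCA (environment x brain x symptoms).

The rank-one multi-block fit maximizes the design-weighted sum of pairwise
variate covariances sum_{j<k} d_jk cov(X_j w_j, X_k w_k) under per-block
unit-norm and L1 bounds, by cyclic soft-thresholded block updates (Horst
scheme, fully connected design by default). The surrounding protocol is the
same as the two-view pipeline -- half-sample stability selection (threshold
85% here), unpenalized refit on the stable sets, permutation inference and
projection deflation per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .pipeline import PipelineConfig, _deflate_view
from .scca import _sparse_unit

__all__ = ["MsccaMode", "MsccaResult", "sgcca_rank1", "run_mscca_pipeline"]


@dataclass
class MsccaMode:
    mode_index: int
    stable_sets: list            # per block, indices into that block's columns
    freqs: list
    weights: list                # per block, full-space unit vectors
    pairwise_r_train: dict       # ("env","brain") etc. -> r
    pairwise_r_test: dict
    pairwise_p_perm: dict
    objective_p_perm: float
    p_fdr: float = np.nan


@dataclass
class MsccaResult:
    modes: list = field(default_factory=list)
    n_attempted: int = 0
    stopped_reason: str = ""


def _default_design(n_blocks: int) -> np.ndarray:
    d = np.ones((n_blocks, n_blocks)) - np.eye(n_blocks)
    return d


def sgcca_rank1(
    blocks: list[np.ndarray],
    sparsities: list[float] | float = 0.5,
    design: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
):
    """Rank-one sparse generalized CCA by cyclic block ascent.

    Each update w_j <- normalize(soft_threshold(sum_k d_jk X_j' X_k w_k /
    (n-1), lam_j)) maximizes the objective over block j under its
    constraints, so the objective is monotone non-decreasing. Deterministic:
    blocks are initialized from their leading principal direction.
    """
    J = len(blocks)
    if J < 2:
        raise ValueError("need at least two blocks")
    if design is None:
        design = _default_design(J)
    design = np.asarray(design, dtype=float)
    if not np.allclose(design, design.T) or np.any(np.diag(design) != 0):
        raise ValueError("design must be symmetric with zero diagonal")
    # connectivity check
    reach = np.linalg.matrix_power(design + np.eye(J), J) > 0
    if not reach.all():
        raise ValueError("disconnected design matrix")
    if np.isscalar(sparsities):
        sparsities = [float(sparsities)] * J
    n = blocks[0].shape[0]
    Xs = [b - b.mean(axis=0) for b in blocks]
    cs = [s * np.sqrt(b.shape[1]) for s, b in zip(sparsities, Xs)]
    ws = []
    for X, c in zip(Xs, cs):
        # leading principal direction by deterministic power iteration
        w0 = np.ones(X.shape[1]) / np.sqrt(X.shape[1])
        for _ in range(8):
            w0 = X.T @ (X @ w0)
            w0 /= np.linalg.norm(w0)
        if np.isfinite(c):
            w0 = _sparse_unit(w0, c)  # feasible start so ascent holds from cycle one
        ws.append(w0)
    variates = [X @ w for X, w in zip(Xs, ws)]

    def objective():
        obj = 0.0
        for j in range(J):
            for k in range(j + 1, J):
                if design[j, k]:
                    obj += design[j, k] * float(variates[j] @ variates[k]) / (n - 1)
        return obj

    prev = objective()
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        delta = 0.0
        for j in range(J):
            target = np.zeros(n)
            for k in range(J):
                if design[j, k]:
                    target += design[j, k] * variates[k]
            v = Xs[j].T @ target / (n - 1)
            if not np.any(v):
                continue
            w_new = _sparse_unit(v, cs[j]) if np.isfinite(cs[j]) else v / np.linalg.norm(v)
            delta = max(delta, np.abs(w_new - ws[j]).max())
            ws[j] = w_new
            variates[j] = Xs[j] @ w_new
        obj = objective()
        assert obj >= prev - 1e-9, "cyclic ascent must not decrease the objective"
        prev = obj
        if delta < tol:
            converged = True
            break
    return ws, prev, it, converged


def _pair_labels(names):
    J = len(names)
    return [(names[j], names[k]) for j in range(J) for k in range(j + 1, J)]


def _pair_corrs(blocks, ws, names) -> dict:
    variates = [b @ w for b, w in zip(blocks, ws)]
    out = {}
    for a, bname in _pair_labels(names):
        u = variates[names.index(a)]
        v = variates[names.index(bname)]
        if u.std() == 0 or v.std() == 0:
            out[(a, bname)] = 0.0
        else:
            out[(a, bname)] = float(np.corrcoef(u, v)[0, 1])
    return out


def _mscca_select_refit(blocks, config: PipelineConfig, rng):
    """Per-block stability selection then unpenalized refit on stable sets."""
    n = blocks[0].shape[0]
    m = max(2, int(round(config.resample_fraction * n)))
    hits = [np.zeros(b.shape[1]) for b in blocks]
    for _ in range(config.n_resamples):
        idx = rng.choice(n, size=m, replace=config.resample_with_replacement)
        ws, *_ = sgcca_rank1([b[idx] for b in blocks], sparsities=config.sparsity)
        for h, w in zip(hits, ws):
            h += w != 0
    freqs = [h / config.n_resamples for h in hits]
    stable = [np.flatnonzero(f >= config.stability_threshold) for f in freqs]
    if any(len(s) == 0 for s in stable):
        return stable, freqs, None, 0.0
    sub_ws, obj, *_ = sgcca_rank1([b[:, s] for b, s in zip(blocks, stable)], sparsities=np.inf)
    full_ws = []
    for b, s, w in zip(blocks, stable, sub_ws):
        full = np.zeros(b.shape[1])
        full[s] = w
        full_ws.append(full)
    return stable, freqs, full_ws, obj


def run_mscca_pipeline(
    env_train: np.ndarray,
    brain_train: np.ndarray,
    sym_train: np.ndarray,
    env_test: np.ndarray,
    brain_test: np.ndarray,
    sym_test: np.ndarray,
    config: PipelineConfig | None = None,
) -> MsccaResult:
    """Multi-mode three-block pipeline with deflation and FDR across modes.

    Mode significance is gated on the permutation p of the refit objective
    under row permutation of the symptom block (selection and refit re-run
    per permutation); per-pair permutation p-values are reported from the
    same null. Brain matrices are expected residualized for intracranial
    volume upstream.
    """
    if config is None:
        config = PipelineConfig(stability_threshold=0.85)
    names = ["env", "brain", "symptoms"]
    rng = np.random.default_rng(config.seed)
    tr = [env_train.copy(), brain_train.copy(), sym_train.copy()]
    te = [env_test.copy(), brain_test.copy(), sym_test.copy()]
    result = MsccaResult()
    for mode_idx in range(config.max_modes):
        result.n_attempted = mode_idx + 1
        stable, freqs, ws, obj = _mscca_select_refit(tr, config, rng)
        if ws is None:
            result.stopped_reason = "no stable signal"
            break
        r_train = _pair_corrs(tr, ws, names)
        perm_obj_ge = 0
        perm_pair_ge = {k: 0 for k in r_train}
        for _ in range(config.n_perm):
            perm = rng.permutation(tr[2].shape[0])
            tr_p = [tr[0], tr[1], tr[2][perm]]
            _, _, ws_p, obj_p = _mscca_select_refit(tr_p, config, rng)
            if ws_p is None:
                continue  # contributes 0 (below any positive observed statistic)
            if obj_p >= obj:
                perm_obj_ge += 1
            r_p = _pair_corrs(tr_p, ws_p, names)
            for k in perm_pair_ge:
                if abs(r_p[k]) >= abs(r_train[k]):
                    perm_pair_ge[k] += 1
        p_obj = (1 + perm_obj_ge) / (1 + config.n_perm)
        if p_obj > config.alpha:
            result.stopped_reason = "permutation non-significant"
            break
        r_test = _pair_corrs(te, ws, names)
        result.modes.append(
            MsccaMode(
                mode_index=mode_idx,
                stable_sets=stable,
                freqs=freqs,
                weights=ws,
                pairwise_r_train=r_train,
                pairwise_r_test=r_test,
                pairwise_p_perm={k: (1 + v) / (1 + config.n_perm) for k, v in perm_pair_ge.items()},
                objective_p_perm=p_obj,
            )
        )
        tr = [_deflate_view(b, w) for b, w in zip(tr, ws)]
        te = [_deflate_view(b, w) for b, w in zip(te, ws)]
    else:
        result.stopped_reason = "max_modes reached"
    if result.modes:
        _, p_adj, *_ = multipletests([m.objective_p_perm for m in result.modes], method="fdr_bh")
        for m, p in zip(result.modes, p_adj):
            m.p_fdr = float(p)
    return result
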