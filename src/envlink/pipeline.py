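"""The multi-stage sparse-CCA protocol with stability selection.

Protocol for one dataset (environment categories X, symptoms Y):

1.  split participants 90/10 into train and test;
2.  draw half-sample resamples of the training data (without replacement);
3.  run the rank-one sparse CCA on each resample (sparsity 0.5 per view);
4.  keep features whose weight is non-zero in >= 90% of resamples;
5.  refit an unpenalized CCA on the stable feature sets;
6.  assess train significance by re-running steps 2-5 on row-permuted data
    (one-sided permutation p);
7.  apply the trained weights to the test split;
8.  assess test significance by permuting test rows under fixed weights.

Significant modes are removed by projection deflation of both views (train
and test) and the search repeats until non-significance; Benjamini-Hochberg
FDR is applied across the test p-values of the extracted modes. The
cross-loading decomposition attributes each symptom group's explained
variance (EV, squared cross-loading x 100) to the environmental profiles
(FEV, summing to 100% per group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .scca import canonical_correlation, cca_unpenalized, pmd_rank1, projection_deflate

__all__ = [
    "PipelineConfig",
    "StabilityResult",
    "ModeResult",
    "PipelineResult",
    "split_train_test",
    "stability_select",
    "permutation_test_train",
    "evaluate_test",
    "run_multi_mode",
    "crossloadings_ev_fev",
    "reliability_suite",
]


@dataclass
class PipelineConfig:
    n_resamples: int = 100
    resample_fraction: float = 0.5
    stability_threshold: float = 0.90
    sparsity: float = 0.5
    n_perm: int = 1000
    train_fraction: float = 0.9
    alpha: float = 0.05
    alpha_fdr: float = 0.05
    max_modes: int = 5
    resample_with_replacement: bool = False
    # "covariance" re-applies the sparse algorithm with the L1 constraint
    # released (leading singular pair of the cross-covariance); "cca" uses
    # the whitened first canonical pair. The covariance refit is the default:
    # for correlated stable sets the whitened in-sample optimum is nearly
    # flat, which lets refit weights wander and leaves large deflation
    # residues at moderate sample sizes.
    refit_method: str = "covariance"
    refit_ridge: float = 1e-6  # whitening ridge when refit_method="cca"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.stability_threshold <= 1):
            raise ValueError("stability_threshold must lie in [0, 1]")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class StabilityResult:
    stable_x: np.ndarray  # indices into X columns
    stable_y: np.ndarray
    freq_x: np.ndarray    # per-feature non-zero selection frequency
    freq_y: np.ndarray

    @property
    def has_signal(self) -> bool:
        return len(self.stable_x) > 0 and len(self.stable_y) > 0


@dataclass
class ModeResult:
    mode_index: int
    stable_x: np.ndarray
    stable_y: np.ndarray
    freq_x: np.ndarray
    freq_y: np.ndarray
    w_x: np.ndarray  # refit weights embedded in full feature space, unit norm
    w_y: np.ndarray
    r_train: float
    p_perm_train: float
    r_test: float
    p_perm_test: float
    p_fdr: float = np.nan
    # canonical variates on the (deflated) matrices the mode was extracted from
    u_train_x: np.ndarray | None = None
    u_train_y: np.ndarray | None = None
    u_test_x: np.ndarray | None = None
    u_test_y: np.ndarray | None = None


@dataclass
class PipelineResult:
    modes: list[ModeResult] = field(default_factory=list)
    n_attempted: int = 0
    stopped_reason: str = ""

    @property
    def n_significant(self) -> int:
        return len(self.modes)


def split_train_test(ids, train_fraction: float, seed: int):
    """Disjoint, exhaustive, seeded train/test split of participant IDs."""
    ids = np.asarray(ids)
    if len(ids) < 10:
        raise ValueError("need at least 10 participants to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    return ids[np.sort(perm[:n_train])], ids[np.sort(perm[n_train:])]


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def stability_select(X: np.ndarray, Y: np.ndarray, config: PipelineConfig, rng=None) -> StabilityResult:
    """Half-sample resampling + sparse CCA; keep features selected >= tau.

    Each resample is a fraction (default half) of the training rows drawn
    without replacement; the sparse rank-one fit is run on the recentered
    resample and per-feature non-zero weight frequencies accumulated.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    m = max(2, int(round(config.resample_fraction * n)))
    hits_x = np.zeros(X.shape[1])
    hits_y = np.zeros(Y.shape[1])
    for _ in range(config.n_resamples):
        idx = rng.choice(n, size=m, replace=config.resample_with_replacement)
        sw = pmd_rank1(_center(X[idx]), _center(Y[idx]), s_x=config.sparsity, s_y=config.sparsity)
        hits_x += sw.w_x != 0
        hits_y += sw.w_y != 0
    freq_x = hits_x / config.n_resamples
    freq_y = hits_y / config.n_resamples
    return StabilityResult(
        stable_x=np.flatnonzero(freq_x >= config.stability_threshold),
        stable_y=np.flatnonzero(freq_y >= config.stability_threshold),
        freq_x=freq_x,
        freq_y=freq_y,
    )


def _select_and_refit(X: np.ndarray, Y: np.ndarray, config: PipelineConfig, rng):
    """Steps 2-5: stability selection then unpenalized refit.

    Returns (StabilityResult, full-space w_x, w_y, r) or r = 0.0 with None
    weights when either stable set is empty.
    """
    sel = stability_select(X, Y, config, rng)
    if not sel.has_signal:
        return sel, None, None, 0.0
    Xs, Ys = X[:, sel.stable_x], Y[:, sel.stable_y]
    if config.refit_method == "covariance":
        sw = pmd_rank1(_center(Xs), _center(Ys), s_x=1.0, s_y=1.0)
        sub_wx, sub_wy = sw.w_x, sw.w_y
    elif config.refit_method == "cca":
        fit = cca_unpenalized(Xs, Ys, ridge_eps=config.refit_ridge)
        sub_wx, sub_wy = fit.w_x, fit.w_y
    else:
        raise ValueError(f"unknown refit_method: {config.refit_method}")
    w_x = np.zeros(X.shape[1])
    w_x[sel.stable_x] = sub_wx
    w_y = np.zeros(Y.shape[1])
    w_y[sel.stable_y] = sub_wy
    r = canonical_correlation(X, Y, w_x, w_y)
    if r < 0:
        w_y, r = -w_y, -r
    return sel, w_x, w_y, r


def permutation_test_train(
    X: np.ndarray, Y: np.ndarray, config: PipelineConfig, r_obs: float, rng=None
) -> float:
    """One-sided train permutation p, re-running selection per permutation.

    Y rows are shuffled and the full select-and-refit procedure repeated;
    permutations with an empty stable set contribute r_perm = 0.
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_ge = 0
    for _ in range(config.n_perm):
        Yp = Y[rng.permutation(Y.shape[0])]
        _, _, _, r_perm = _select_and_refit(X, Yp, config, rng)
        if r_perm >= r_obs:
            n_ge += 1
    return (1 + n_ge) / (1 + config.n_perm)


def evaluate_test(
    w_x: np.ndarray,
    w_y: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    n_perm: int,
    rng=None,
):
    """Out-of-sample r under fixed weights, with a row-permutation p.

    Only the symptom view's rows are shuffled; weights are never
    re-estimated. With ``n_perm`` = 0 the p-value is reported as NaN.
    """
    if X_test.shape[1] != len(w_x) or Y_test.shape[1] != len(w_y):
        raise ValueError("weight length does not match test feature count")
    if rng is None:
        rng = np.random.default_rng(0)
    r_test = canonical_correlation(X_test, Y_test, w_x, w_y)
    if n_perm == 0:
        return r_test, np.nan
    u = X_test @ w_x
    v = Y_test @ w_y
    n_ge = 0
    for _ in range(n_perm):
        r_perm = np.corrcoef(u, v[rng.permutation(len(v))])[0, 1]
        if r_perm >= r_test:
            n_ge += 1
    return r_test, (1 + n_ge) / (1 + n_perm)


def _deflate_view(M: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Orthogonalized projection deflation of one data view.

    Removes the extracted variate u = Mw from the rows and the weight
    direction from the columns: M' = (I - uu'/u'u) M (I - ww'). Afterwards
    M'w = 0 and every later variate M'v is exactly uncorrelated with u.
    """
    u = M @ w
    uu = u @ u
    if uu > 0:
        M = M - np.outer(u, u @ M) / uu
    return projection_deflate(M, w)


def run_multi_mode(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    config: PipelineConfig,
) -> PipelineResult:
    """Sequential mode extraction with deflation and FDR across modes."""
    rng = np.random.default_rng(config.seed)
    # center on training means (exact column centering keeps successive
    # training variates exactly mean-zero through the deflations)
    mx, my = X_train.mean(axis=0), Y_train.mean(axis=0)
    Xd, Yd = X_train - mx, Y_train - my
    Xt, Yt = X_test - mx, Y_test - my
    result = PipelineResult()
    for mode_idx in range(config.max_modes):
        result.n_attempted = mode_idx + 1
        sel, w_x, w_y, r_train = _select_and_refit(Xd, Yd, config, rng)
        if w_x is None:
            result.stopped_reason = "no stable signal"
            break
        p_train = permutation_test_train(Xd, Yd, config, r_train, rng)
        if p_train > config.alpha:
            result.stopped_reason = "train permutation non-significant"
            break
        r_test, p_test = evaluate_test(w_x, w_y, Xt, Yt, config.n_perm, rng)
        result.modes.append(
            ModeResult(
                mode_index=mode_idx,
                stable_x=sel.stable_x,
                stable_y=sel.stable_y,
                freq_x=sel.freq_x,
                freq_y=sel.freq_y,
                w_x=w_x,
                w_y=w_y,
                r_train=r_train,
                p_perm_train=p_train,
                r_test=r_test,
                p_perm_test=p_test,
                u_train_x=Xd @ w_x,
                u_train_y=Yd @ w_y,
                u_test_x=Xt @ w_x,
                u_test_y=Yt @ w_y,
            )
        )
        Xd = _deflate_view(Xd, w_x)
        Yd = _deflate_view(Yd, w_y)
        Xt = _deflate_view(Xt, w_x)
        Yt = _deflate_view(Yt, w_y)
    else:
        result.stopped_reason = "max_modes reached"
    if result.modes:
        _, p_adj, *_ = multipletests([m.p_perm_test for m in result.modes], method="fdr_bh")
        for m, p in zip(result.modes, p_adj):
            m.p_fdr = float(p)
    return result


def crossloadings_ev_fev(X_categories: np.ndarray, symptom_variates: np.ndarray, mode_feature_sets):
    """Cross-loading EV and FEV decomposition.

    ``symptom_variates`` holds one column per mode (the symptom-view
    variate); ``mode_feature_sets`` gives each mode's stable environment
    feature indices. Returns (crossloadings, ev, fev) where fev[m, k] is the
    percentage of symptom group k's total cross-loading EV attributable to
    profile m; columns of fev sum to 100.
    """
    Xc = _center(X_categories)
    V = _center(np.atleast_2d(symptom_variates.T).T)
    p, K = Xc.shape[1], V.shape[1]
    rho = np.empty((p, K))
    for k in range(K):
        v = V[:, k]
        if v.std() == 0:
            raise ValueError("zero-variance symptom variate")
        rho[:, k] = (Xc * v[:, None]).mean(axis=0) / (Xc.std(axis=0) * v.std())
    ev = 100.0 * rho**2
    M = len(mode_feature_sets)
    mass = np.empty((M, K))
    for m_idx, feats in enumerate(mode_feature_sets):
        mass[m_idx] = ev[np.asarray(feats, dtype=int)].sum(axis=0)
    total = mass.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("no crossloading mass for at least one symptom group")
    fev = 100.0 * mass / total
    return rho, ev, fev


def reliability_suite(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    config: PipelineConfig,
    sex: np.ndarray | None = None,
    fractions=tuple(np.round(np.arange(0.1, 1.51, 0.1), 2)),
    n_reps: int = 10,
) -> dict:
    """Robustness re-invocations of the select-and-refit core.

    (1) subsample-size sweep: canonical r over bootstrap subsamples of
    10-150% of the training data; (2) loading stability: correlation of
    resampled refit weights with the full-data weights; (3) sex-stratified
    refits with cross-sex weight application. No new math -- every entry is
    a re-run of steps 2-5 with altered sampling.
    """
    rng = np.random.default_rng(config.seed + 17)
    n = X_train.shape[0]
    _, w_x_full, w_y_full, r_full = _select_and_refit(X_train, Y_train, config, rng)
    report: dict = {"r_full": r_full, "sweep": {}, "loading_correlations": [], "sex": None}
    max_p = max(X_train.shape[1], Y_train.shape[1])
    for frac in fractions:
        m = int(round(frac * n))
        if m <= max_p:
            report["sweep"][frac] = {"skipped": "subsample smaller than feature count"}
            continue
        rs = []
        for _ in range(n_reps):
            idx = rng.choice(n, size=m, replace=True)
            _, wx, wy, r = _select_and_refit(X_train[idx], Y_train[idx], config, rng)
            rs.append(r)
            if w_x_full is not None and wx is not None and frac == 1.0:
                report["loading_correlations"].append(
                    float(np.corrcoef(np.concatenate([wx, wy]), np.concatenate([w_x_full, w_y_full]))[0, 1])
                )
        report["sweep"][frac] = {"mean_r": float(np.mean(rs)), "sd_r": float(np.std(rs, ddof=1))}
    if sex is not None and w_x_full is not None:
        sex = np.asarray(sex)
        per_sex = {}
        for label in (0, 1):
            mask = sex == label
            _, wx, wy, r = _select_and_refit(X_train[mask], Y_train[mask], config, rng)
            per_sex[label] = {"r": r, "w_x": wx, "w_y": wy}
        cross = {}
        for a, b in ((0, 1), (1, 0)):
            wa = per_sex[a]
            if wa["w_x"] is not None:
                mask = sex == b
                cross[f"{a}->{b}"] = canonical_correlation(
                    X_train[mask], Y_train[mask], wa["w_x"], wa["w_y"]
                )
        report["sex"] = {"r": {k: v["r"] for k, v in per_sex.items()}, "cross_r": cross}
    return report
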