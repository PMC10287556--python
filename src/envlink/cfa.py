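"""One-factor confirmatory factor analysis with cross-validated scoring.

Correlated item groups (e.g. five sound-pollution measures) are collapsed
into a single latent category: a one-factor measurement model
Sigma(theta) = lambda lambda' + diag(psi) is fitted by maximum likelihood,
items with the weakest loading are pruned until the model reaches excellent
fit (TLI > 0.95, CFI > 0.95, RMSEA < 0.06, SRMR < 0.08), and latent scores
for held-out participants are produced by the regression method. Scoring is
done out-of-fold so no participant's latent value is estimated from a model
fitted on their own data.

Identification fixes the factor variance at 1 (all loadings free); the sign
convention makes the sum of loadings non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datatypes import FeatureTable

__all__ = [
    "CfaModel",
    "LatentCategorySpec",
    "DEFAULT_FIT_CRITERIA",
    "fit_cfa_one_factor",
    "cfa_fit_indices",
    "indices_from_chi2",
    "cfa_item_prune",
    "cfa_scores",
    "build_categories",
]

PSI_FLOOR = 1e-6

#: excellent-fit thresholds used to stop the pruning loop
DEFAULT_FIT_CRITERIA = {"tli": 0.95, "cfi": 0.95, "rmsea": 0.06, "srmr": 0.08}


@dataclass
class CfaModel:
    item_names: list[str]
    loadings: np.ndarray
    uniquenesses: np.ndarray
    item_means: np.ndarray
    fit: dict
    n_fit: int
    converged: bool
    gradient_norm: float
    heywood: bool = False
    pruning_trail: list = field(default_factory=list)

    @property
    def sigma(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) + np.diag(self.uniquenesses)


def _fml(S: np.ndarray, sigma: np.ndarray) -> float:
    """ML discrepancy ln|Sigma| + tr(S Sigma^-1) - ln|S| - p."""
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        return np.inf
    return logdet_m + float(np.trace(np.linalg.solve(sigma, S))) - logdet_s - p


def fit_cfa_one_factor(
    items: FeatureTable | None = None,
    *,
    S: np.ndarray | None = None,
    n: int | None = None,
    item_names: list[str] | None = None,
    item_means: np.ndarray | None = None,
    max_iter: int = 500,
) -> CfaModel:
    """Maximum-likelihood one-factor fit.

    Either an item table or a covariance matrix ``S`` with sample size ``n``
    may be supplied. Uniquenesses are bounded below at a small positive
    floor; hitting the floor (a Heywood case) is flagged, not fatal.
    """
    if items is not None:
        df = items.data.dropna()
        S = np.cov(df.to_numpy(), rowvar=False, ddof=1)
        n = len(df)
        item_names = list(df.columns)
        item_means = df.to_numpy().mean(axis=0)
    if S is None or n is None:
        raise ValueError("supply either an item table or (S, n)")
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if p < 3:
        raise ValueError("one-factor CFA needs >= 3 items for positive df")
    if n <= p:
        raise ValueError("sample size must exceed the number of items")
    if item_names is None:
        item_names = [f"item{j}" for j in range(p)]
    if item_means is None:
        item_means = np.zeros(p)

    # start values: first principal component scaled to its eigenvalue share
    evals, evecs = np.linalg.eigh(S)
    lam0 = evecs[:, -1] * np.sqrt(max(evals[-1] - np.mean(evals[:-1]), 0.1))
    if lam0.sum() < 0:
        lam0 = -lam0
    psi0 = np.maximum(np.diag(S) - lam0**2, 0.05 * np.diag(S))

    def objective(theta):
        lam, psi = theta[:p], theta[p:]
        sigma = np.outer(lam, lam) + np.diag(psi)
        f = _fml(S, sigma)
        if not np.isfinite(f):
            return 1e10, np.zeros(2 * p)
        sigma_inv = np.linalg.inv(sigma)
        d_sigma = sigma_inv - sigma_inv @ S @ sigma_inv  # dF/dSigma
        g_lam = 2.0 * d_sigma @ lam
        g_psi = np.diag(d_sigma)
        return f, np.concatenate([g_lam, g_psi])

    bounds = [(None, None)] * p + [(PSI_FLOOR, None)] * p
    res = minimize(
        objective,
        np.concatenate([lam0, psi0]),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    lam, psi = res.x[:p], np.maximum(res.x[p:], PSI_FLOOR)
    if lam.sum() < 0:
        lam = -lam
    heywood = bool(np.any(psi <= PSI_FLOOR * 1.01))
    f_opt = _fml(S, np.outer(lam, lam) + np.diag(psi))
    model = CfaModel(
        item_names=list(item_names),
        loadings=lam,
        uniquenesses=psi,
        item_means=np.asarray(item_means, dtype=float),
        fit={},
        n_fit=int(n),
        converged=bool(res.success or np.linalg.norm(res.jac) < 1e-5),
        gradient_norm=float(np.linalg.norm(res.jac)),
        heywood=heywood,
    )
    if not model.converged:
        raise RuntimeError(f"CFA did not converge: {res.message} (|grad|={model.gradient_norm:.2e})")
    if p > 3:
        model.fit = cfa_fit_indices(model, S, n, f_opt=f_opt)
    else:
        # p = 3 is just-identified (df = 0): chi2 ~ 0, indices undefined
        model.fit = {
            "chi2": float((n - 1) * f_opt), "df": 0,
            "cfi": np.nan, "tli": np.nan, "rmsea": np.nan, "srmr": np.nan,
        }
    return model


def indices_from_chi2(chi2: float, df: int, chi2_b: float, df_b: int, n: int) -> dict:
    """CFI, TLI and RMSEA from the fitted and baseline chi-squared values."""
    if df <= 0 or df_b <= 0:
        raise ValueError("fit indices undefined at df <= 0")
    d = max(chi2 - df, 0.0)
    d_b = max(chi2_b - df_b, 0.0)
    cfi = 1.0 - d / max(d_b, d, np.finfo(float).tiny)
    ratio_b = chi2_b / df_b
    tli = (ratio_b - chi2 / df) / (ratio_b - 1.0)
    rmsea = np.sqrt(d / (df * (n - 1)))
    return {"cfi": float(cfi), "tli": float(tli), "rmsea": float(rmsea)}


def cfa_fit_indices(model: CfaModel, S: np.ndarray, n: int, f_opt: float | None = None) -> dict:
    """Chi-squared and the standard incremental/absolute fit indices.

    The baseline model is the independence model (diagonal Sigma);
    chi2 = (n-1) * F_ML at the respective optimum.
    """
    p = S.shape[0]
    df = p * (p + 1) // 2 - 2 * p
    if df <= 0:
        raise ValueError("fit indices undefined at df <= 0")
    if f_opt is None:
        f_opt = _fml(S, model.sigma)
    chi2 = (n - 1) * f_opt
    # independence baseline: Sigma_b = diag(S) is its own ML optimum
    f_base = _fml(S, np.diag(np.diag(S)))
    chi2_b = (n - 1) * f_base
    df_b = p * (p + 1) // 2 - p
    idx = indices_from_chi2(chi2, df, chi2_b, df_b, n)
    # SRMR over the lower triangle incl. diagonal of standardized residuals
    sd = np.sqrt(np.diag(S))
    resid = (S - model.sigma) / np.outer(sd, sd)
    tril = np.tril_indices(p)
    srmr = np.sqrt(np.mean(resid[tril] ** 2))
    return {
        "chi2": float(chi2),
        "df": int(df),
        "chi2_baseline": float(chi2_b),
        "df_baseline": int(df_b),
        "cfi": idx["cfi"],
        "tli": idx["tli"],
        "rmsea": idx["rmsea"],
        "srmr": float(srmr),
    }


def _criteria_met(fit: dict, criteria: dict) -> bool:
    if fit["df"] <= 0:  # indices undefined: cannot certify excellent fit
        return False
    return (
        fit["tli"] > criteria["tli"]
        and fit["cfi"] > criteria["cfi"]
        and fit["rmsea"] < criteria["rmsea"]
        and fit["srmr"] < criteria["srmr"]
    )


def cfa_item_prune(
    items: FeatureTable,
    criteria: dict | None = None,
    min_items: int = 3,
) -> CfaModel:
    """Iteratively drop the weakest-loading item until excellent fit.

    Each round fits the one-factor model and tests the fit criteria; on
    failure the item with the smallest absolute loading is removed and the
    model refitted. Raises if the criteria are still unmet at ``min_items``,
    carrying the best model found in the exception.
    """
    criteria = dict(DEFAULT_FIT_CRITERIA if criteria is None else criteria)
    current = items
    trail = []
    best = None
    while True:
        model = fit_cfa_one_factor(current)
        trail.append(
            {"items": list(model.item_names), "fit": dict(model.fit), "met": _criteria_met(model.fit, criteria)}
        )
        if best is None or model.fit["rmsea"] < best.fit["rmsea"]:
            best = model
        if _criteria_met(model.fit, criteria):
            model.pruning_trail = trail
            return model
        if current.n_features <= min_items:
            err = RuntimeError(
                f"fit criteria never met with >= {min_items} items "
                f"(best RMSEA {best.fit['rmsea']:.4f} on {len(best.item_names)} items)"
            )
            err.best_model = best
            err.trail = trail
            raise err
        drop = model.item_names[int(np.argmin(np.abs(model.loadings)))]
        current = current.select_features([c for c in current.feature_names if c != drop])


def cfa_scores(model: CfaModel, new_items: FeatureTable) -> pd.Series:
    """Regression-method factor scores f = lambda' Sigma^-1 (x - mean)."""
    if list(new_items.feature_names) != list(model.item_names):
        raise ValueError("item columns do not match the fitted model")
    x = new_items.values - model.item_means
    coef = np.linalg.solve(model.sigma, model.loadings)
    return pd.Series(x @ coef, index=new_items.participant_ids, name="score")


@dataclass
class LatentCategorySpec:
    category_name: str
    member_item_names: list[str]
    min_items: int = 3


def build_categories(
    raw_env: FeatureTable,
    specs: list[LatentCategorySpec],
    n_folds: int = 10,
    seed: int = 0,
    criteria: dict | None = None,
) -> FeatureTable:
    """Collapse raw items into latent categories with out-of-fold scoring.

    Single-item categories are copied through. For a multi-item category,
    participants are split into ``n_folds`` folds; for each fold the pruned
    one-factor model is fitted on the other folds and used to score the
    held-out fold, so every participant's latent value is produced exactly
    once, by a model that never saw them.
    """
    all_members = [m for s in specs for m in s.member_item_names]
    if sorted(all_members) != sorted(raw_env.feature_names):
        raise ValueError("category specs must partition the raw item list")
    rng = np.random.default_rng(seed)
    n = raw_env.n_participants
    fold_of = rng.permuted(np.arange(n) % n_folds)
    out = pd.DataFrame(index=raw_env.participant_ids)
    for spec in specs:
        if len(spec.member_item_names) == 1:
            out[spec.category_name] = raw_env.data[spec.member_item_names[0]]
            continue
        items = raw_env.select_features(spec.member_item_names)
        scores = pd.Series(np.nan, index=items.participant_ids)
        for fold in range(n_folds):
            train = items.data.iloc[fold_of != fold]
            test = items.data.iloc[fold_of == fold]
            try:
                model = cfa_item_prune(
                    FeatureTable(train, items.view_label), criteria=criteria, min_items=spec.min_items
                )
            except RuntimeError as err:
                raise RuntimeError(f"category {spec.category_name!r}: {err}") from err
            scores.loc[test.index] = cfa_scores(
                model, FeatureTable(test[model.item_names], items.view_label)
            ).to_numpy()
        assert not scores.isna().any(), "every participant must be scored exactly once"
        out[spec.category_name] = scores
    return FeatureTable(out, raw_env.view_label or "environment_categories")
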