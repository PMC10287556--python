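"""Moderated mediation ("Model 59"): the moderator acts on all three paths.

Two OLS equations are fitted on mean-centered variables:

    M = a0 + a1*X + a2*W + a3*(X*W) + covariates + e_M
    Y = b0 + c'*X + c2*W + c3*(X*W) + b1*M + b2*(M*W) + covariates + e_Y

The conditional indirect effect at moderator value w is
(a1 + a3*w)(b1 + b2*w) and the conditional direct effect is c' + c3*w,
evaluated by default at the 16th/50th/84th sample percentiles of the
centered moderator (low / medium / high genetic risk). Inference uses a
bias-corrected (BC, no acceleration) bootstrap percentile interval; the
explained mediation effect (EME) summarizes the share of the total effect
flowing through the mediator at the median moderator value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Model59Spec",
    "Model59Fit",
    "MediationResult",
    "fit_model59",
    "conditional_effects",
    "bootstrap_bca_ci",
    "explained_mediation_effect",
]


@dataclass
class Model59Spec:
    x: str
    m: str
    y: str
    w: str
    covariates: list[str] = field(default_factory=list)
    percentiles: tuple = (16, 50, 84)
    B: int = 5000
    ci_level: float = 0.95
    center: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        cols = [self.x, self.m, self.y, self.w]
        if len(set(cols)) != 4:
            raise ValueError("x, m, y, w must be distinct columns")
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class Model59Fit:
    a: dict   # mediator equation: a0, a1 (X), a2 (W), a3 (X*W)
    b: dict   # outcome equation: b0, c_prime (X), c2 (W), c3 (X*W), b1 (M), b2 (M*W)
    resid_var_m: float
    resid_var_y: float
    n: int
    w_percentile_values: dict  # percentile -> centered moderator value


def _designs(df: pd.DataFrame, spec: Model59Spec):
    x = df[spec.x].to_numpy(dtype=float)
    m = df[spec.m].to_numpy(dtype=float)
    y = df[spec.y].to_numpy(dtype=float)
    w = df[spec.w].to_numpy(dtype=float)
    if spec.center:
        x = x - x.mean()
        m = m - m.mean()
        w = w - w.mean()
    cov = df[spec.covariates].to_numpy(dtype=float) if spec.covariates else np.empty((len(df), 0))
    one = np.ones(len(df))
    degenerate_w = w.std() == 0
    if degenerate_w:
        # constant moderator: the model reduces to simple mediation
        Zm = np.column_stack([one, x, cov])
        Zy = np.column_stack([one, x, m, cov])
    else:
        Zm = np.column_stack([one, x, w, x * w, cov])
        Zy = np.column_stack([one, x, w, x * w, m, m * w, cov])
    return Zm, Zy, m, y, w, degenerate_w


def _ols(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, res, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        raise ValueError("collinear design in moderated-mediation fit")
    return coef


def fit_model59(data: pd.DataFrame, spec: Model59Spec) -> Model59Fit:
    """Fit both Model-59 equations on the shared complete-case set."""
    cols = [spec.x, spec.m, spec.y, spec.w] + list(spec.covariates)
    df = data[cols].dropna()
    n = len(df)
    if n <= len(cols) + 4:
        raise ValueError("sample too small for the Model-59 parameter count")
    Zm, Zy, m, y, w, degenerate = _designs(df, spec)
    am = _ols(Zm, m)
    by = _ols(Zy, y)
    pct = {p: float(np.percentile(w, p)) for p in spec.percentiles}
    if degenerate:
        a = {"a0": am[0], "a1": am[1], "a2": 0.0, "a3": 0.0}
        b = {"b0": by[0], "c_prime": by[1], "c2": 0.0, "c3": 0.0, "b1": by[2], "b2": 0.0}
    else:
        a = {"a0": am[0], "a1": am[1], "a2": am[2], "a3": am[3]}
        b = {"b0": by[0], "c_prime": by[1], "c2": by[2], "c3": by[3], "b1": by[4], "b2": by[5]}
    return Model59Fit(
        a=a,
        b=b,
        resid_var_m=float(np.var(m - Zm @ am, ddof=Zm.shape[1])),
        resid_var_y=float(np.var(y - Zy @ by, ddof=Zy.shape[1])),
        n=n,
        w_percentile_values=pct,
    )


def conditional_effects(fit: Model59Fit, w_values=None) -> pd.DataFrame:
    """Conditional indirect (a1+a3*w)(b1+b2*w) and direct c'+c3*w effects."""
    if w_values is None:
        w_values = fit.w_percentile_values
    if not isinstance(w_values, dict):
        w_values = {float(w): float(w) for w in np.atleast_1d(w_values)}
    rows = []
    for label, w in w_values.items():
        indirect = (fit.a["a1"] + fit.a["a3"] * w) * (fit.b["b1"] + fit.b["b2"] * w)
        direct = fit.b["c_prime"] + fit.b["c3"] * w
        rows.append({"w_label": label, "w": w, "indirect": indirect, "direct": direct})
    return pd.DataFrame(rows).set_index("w_label")


@dataclass
class MediationResult:
    fit: Model59Fit
    effects: pd.DataFrame  # per percentile: indirect, direct, CI bounds, significance
    eme_percent: float
    B_effective: int
    n_redrawn: int
    ci_level: float


def bootstrap_bca_ci(data: pd.DataFrame, spec: Model59Spec) -> MediationResult:
    """Bias-corrected bootstrap CIs for the conditional indirect effects.

    Participants are resampled with replacement B times and both equations
    refitted; for each moderator percentile the BC interval takes bootstrap
    percentiles at Phi(2*z0 +/- z_{alpha/2}) with z0 = Phi^-1(frac of
    bootstrap estimates below the point estimate). Moderator percentile
    values are held fixed at the original sample's. Singular resamples are
    redrawn (counted, capped at 10*B).
    """
    if spec.B < 1000:
        warnings.warn("fewer than 1,000 bootstrap resamples gives unstable CIs", stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    cols = [spec.x, spec.m, spec.y, spec.w] + list(spec.covariates)
    df = data[cols].dropna().reset_index(drop=True)
    point_fit = fit_model59(df, spec)
    w_vals = point_fit.w_percentile_values
    point = conditional_effects(point_fit, w_vals)

    Zm, Zy, m, y, _, degenerate = _designs(df, spec)
    n = len(df)
    boot = np.empty((spec.B, len(w_vals)))
    n_redrawn = 0
    b = 0
    attempts = 0
    while b < spec.B and attempts < 10 * spec.B:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        Zmb, Zyb = Zm[idx], Zy[idx]
        try:
            am = np.linalg.solve(Zmb.T @ Zmb, Zmb.T @ m[idx])
            by = np.linalg.solve(Zyb.T @ Zyb, Zyb.T @ y[idx])
        except np.linalg.LinAlgError:
            n_redrawn += 1
            continue
        for j, w in enumerate(w_vals.values()):
            if degenerate:
                boot[b, j] = am[1] * by[2]
            else:
                boot[b, j] = (am[1] + am[3] * w) * (by[4] + by[5] * w)
        b += 1
    boot = boot[:b]

    alpha = 1 - spec.ci_level
    z_alpha = norm.ppf(1 - alpha / 2)
    rows = []
    for j, (label, w) in enumerate(w_vals.items()):
        theta_hat = point.loc[label, "indirect"]
        bj = boot[:, j]
        prop = np.clip(np.mean(bj < theta_hat), 1 / (2 * len(bj)), 1 - 1 / (2 * len(bj)))
        z0 = norm.ppf(prop)
        lo_q, hi_q = norm.cdf(2 * z0 - z_alpha), norm.cdf(2 * z0 + z_alpha)
        lo, hi = np.quantile(bj, [lo_q, hi_q])
        rows.append(
            {
                "w_label": label,
                "w": w,
                "indirect": theta_hat,
                "direct": point.loc[label, "direct"],
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    effects = pd.DataFrame(rows).set_index("w_label")
    median_label = spec.percentiles[len(spec.percentiles) // 2]
    eme = explained_mediation_effect(point_fit, w_vals[median_label])
    return MediationResult(
        fit=point_fit,
        effects=effects,
        eme_percent=eme,
        B_effective=b,
        n_redrawn=n_redrawn,
        ci_level=spec.ci_level,
    )


def explained_mediation_effect(fit: Model59Fit, w_median: float) -> float:
    """EME = 100 * indirect / (indirect + direct) at the median moderator.

    Returns NaN (flagged as undefined) when the total effect is within
    1e-6 of zero.
    """
    eff = conditional_effects(fit, {"w": w_median}).iloc[0]
    total = eff["indirect"] + eff["direct"]
    if abs(total) < 1e-6:
        return float("nan")
    return float(100.0 * eff["indirect"] / total)
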