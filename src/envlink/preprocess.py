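"""Variable QC, confound residualization and household de-duplication.

The QC steps mirror standard cohort practice: per-feature outlier masking at
k median absolute deviations, and a near-zero-variance screen for features
whose distribution is dominated by a single value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FeatureTable

__all__ = ["QcReport", "mad_filter", "near_zero_variance", "residualize", "dedup_households"]


@dataclass
class QcReport:
    masked_counts: pd.Series | None = None       # per-feature values masked by the MAD rule
    mad_zero_flags: list = field(default_factory=list)
    nzv_flags: pd.DataFrame | None = None        # freq_ratio, pct_unique, flagged
    completeness: pd.Series | None = None        # per-participant fraction non-missing


def mad_filter(table: FeatureTable, k: float = 4.0, scaled: bool = False):
    """Mask values more than ``k`` median absolute deviations from the median.

    The MAD is the raw median of |x - median| over non-missing values
    (``scaled=True`` applies the 1.4826 normal-consistency factor). Features
    with MAD = 0 are left untouched and flagged. Single-pass semantics:
    medians and MADs come from the input values only.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    df = table.data.copy()
    masked = {}
    zero_flags = []
    for col in df.columns:
        x = df[col]
        obs = x.dropna()
        if obs.empty:
            raise ValueError(f"feature {col!r} is entirely missing")
        med = obs.median()
        mad = (obs - med).abs().median()
        if scaled:
            mad *= 1.4826
        if mad == 0:
            zero_flags.append(col)
            masked[col] = 0
            continue
        out = (x - med).abs() > k * mad
        masked[col] = int(out.sum())
        df.loc[out, col] = np.nan
    report = QcReport(
        masked_counts=pd.Series(masked, name="masked"),
        mad_zero_flags=zero_flags,
        completeness=1.0 - df.isna().mean(axis=1),
    )
    return FeatureTable(df, table.view_label), report


def near_zero_variance(
    table: FeatureTable, freq_cut: float = 95 / 5, unique_cut_pct: float = 10.0
) -> QcReport:
    """Flag features with near-zero variance.

    A feature is flagged when the ratio of the most common value's frequency
    to the second most common is >= ``freq_cut`` AND the percentage of
    distinct values is <= ``unique_cut_pct``; zero-variance features are
    always flagged.
    """
    if table.n_features == 0 or table.n_participants == 0:
        raise ValueError("empty table")
    rows = {}
    for col in table.data.columns:
        obs = table.data[col].dropna()
        counts = obs.value_counts()
        n_unique = len(counts)
        pct_unique = 100.0 * n_unique / len(obs)
        if n_unique <= 1:
            rows[col] = (np.inf, pct_unique, True)
            continue
        ratio = counts.iloc[0] / counts.iloc[1]
        rows[col] = (ratio, pct_unique, bool(ratio >= freq_cut and pct_unique <= unique_cut_pct))
    nzv = pd.DataFrame.from_dict(rows, orient="index", columns=["freq_ratio", "pct_unique", "flagged"])
    return QcReport(nzv_flags=nzv)


def residualize(table: FeatureTable, confounds: FeatureTable, zscore: bool = True) -> FeatureTable:
    """Replace each feature by its least-squares residual on the confounds.

    An intercept is always included. Participants are first restricted to
    complete cases across both tables; with ``zscore`` the residuals are
    standardized to mean 0, sd 1.
    """
    common = table.participant_ids.intersection(confounds.participant_ids)
    sub = table.data.loc[common]
    conf = confounds.data.loc[common]
    keep = ~(sub.isna().any(axis=1) | conf.isna().any(axis=1))
    sub, conf = sub.loc[keep], conf.loc[keep]
    design = np.column_stack([np.ones(len(conf)), conf.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad, cols = [], [np.ones(len(conf))]
        for name in conf.columns:
            trial = np.column_stack(cols + [conf[name].to_numpy()])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(name)
            else:
                cols.append(conf[name].to_numpy())
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, sub.to_numpy(), rcond=None)
    resid = sub.to_numpy() - design @ coef
    if zscore:
        sd = resid.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        resid = (resid - resid.mean(axis=0)) / sd
    return FeatureTable(pd.DataFrame(resid, index=sub.index, columns=sub.columns), table.view_label)


def dedup_households(records: FeatureTable, match_fields: list[str], seed: int):
    """Keep one participant per putative household.

    Participants identical on every ``match_fields`` column form a household
    group; from each group of size >= 2 one member is retained uniformly at
    random (seeded). Participants with missing match fields are treated as
    singletons.

    Returns ``(kept_ids, report)`` where the report counts groups and
    exclusions.
    """
    missing_cols = [f for f in match_fields if f not in records.data.columns]
    if missing_cols:
        raise ValueError(f"match fields absent from records: {missing_cols}")
    rng = np.random.default_rng(seed)
    sub = records.data[match_fields]
    has_na = sub.isna().any(axis=1)
    singles = list(records.data.index[has_na])
    groups = sub.loc[~has_na].groupby(match_fields, sort=True).groups
    kept = list(singles)
    n_multi = 0
    n_excluded = 0
    for _, ids in sorted(groups.items(), key=lambda kv: str(kv[0])):
        ids = list(ids)
        if len(ids) == 1:
            kept.append(ids[0])
        else:
            n_multi += 1
            n_excluded += len(ids) - 1
            kept.append(ids[rng.integers(len(ids))])
    kept_ids = records.data.index[records.data.index.isin(kept)]  # original order
    report = {
        "n_household_groups": n_multi,
        "n_excluded": n_excluded,
        "n_missing_match_fields": int(has_na.sum()),
    }
    return kept_ids, report
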