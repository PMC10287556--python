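"""Dosage-based association testing, LD clumping and gene scores.

A canonical symptom variate from the sparse-CCA stage is regressed on each
variant's effect-allele dosage (additive model, shared covariates), the
resulting hits are thinned by greedy LD clumping (r-squared and distance
gates), and per-gene weighted allele scores -- sum over a gene's index
variants of dosage x GWAS beta -- summarize genetic load. The stratified
correlation test compares the environment-symptom correlation between low
and high gene-score strata with Fisher's z.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FeatureTable, GenotypeMatrix

__all__ = [
    "qc_variants",
    "gwas_linear",
    "bonferroni_threshold",
    "ld_r2",
    "clump",
    "gene_score",
    "stratified_correlation_test",
]


def qc_variants(g: GenotypeMatrix, maf_min: float = 0.001, info_min: float = 0.3) -> GenotypeMatrix:
    """Drop variants with MAF below ``maf_min`` or imputation info below ``info_min``."""
    info = g.variant_info
    keep = (info["maf"] >= maf_min) & (info["info"] >= info_min)
    return g.select_variants(info.index[keep])


def gwas_linear(y: np.ndarray, g: GenotypeMatrix, covariates: FeatureTable | None = None) -> pd.DataFrame:
    """Per-variant additive-model OLS of y on [1, dosage, covariates].

    All variants share the covariate design, so the per-variant fit is done
    by the Frisch-Waugh-Lovell route: y and every dosage column are
    residualized on the covariates once, then each variant needs only a
    simple regression. Identical to the full per-variant OLS solve,
    including the t-distribution p-value with n - k degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != g.dosages.shape[0]:
        raise ValueError("phenotype and genotype cohorts differ in length")
    if covariates is not None:
        C = covariates.data.to_numpy()
        Z = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("collinear covariates")
    else:
        Z = np.ones((n, 1))
    Q, _ = np.linalg.qr(Z)
    G = g.dosages.to_numpy()
    ry = y - Q @ (Q.T @ y)
    RG = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", RG, RG)
    if np.any(gg <= 0):
        bad = g.variant_ids[gg <= 0][0]
        raise ValueError(f"zero-variance dosage after covariate adjustment: {bad}")
    beta = RG.T @ ry / gg
    k = Z.shape[1] + 1  # intercept+covariates plus the dosage term
    df = n - k
    rss = ry @ ry - beta**2 * gg
    se = np.sqrt(np.maximum(rss, 0.0) / df / gg)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {
            "chrom": g.variant_info["chrom"],
            "pos": g.variant_info["pos"],
            "effect_allele": g.variant_info["effect_allele"],
            "other_allele": g.variant_info["other_allele"],
            "beta": beta,
            "se": se,
            "t": t,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "n_used": n,
        },
        index=g.variant_ids,
    )


def bonferroni_threshold(n_variants: int, n_groups: int) -> float:
    """Genome-wide alpha = 0.05 / (n_variants x n_symptom_groups)."""
    if n_variants < 1 or n_groups < 1:
        raise ValueError("counts must be >= 1")
    return 0.05 / (n_variants * n_groups)


def ld_r2(g: GenotypeMatrix, i: str, j: str) -> float:
    """Squared Pearson correlation of the two variants' dosages."""
    a = g.dosages[i].to_numpy()
    b = g.dosages[j].to_numpy()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance dosage")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def clump(
    gwas: pd.DataFrame,
    g: GenotypeMatrix,
    p1: float = 1.0,
    r2: float = 0.5,
    kb: float = 250.0,
) -> list[str]:
    """Greedy LD clumping; returns the index-variant IDs.

    Variants are visited by ascending p (ties broken by position then ID);
    each index removes unassigned variants on the same chromosome within
    ``kb`` kilobases (inclusive) AND with dosage r-squared > ``r2`` against
    it. Variants with p > ``p1`` cannot become an index (p1 = 1 admits all).
    """
    order = gwas.assign(_id=gwas.index).sort_values(["p", "pos", "_id"]).index
    D = g.dosages
    sd = D.std(axis=0)
    assigned: set[str] = set()
    indexes: list[str] = []
    for vid in order:
        if vid in assigned:
            continue
        if gwas.at[vid, "p"] > p1:
            assigned.add(vid)
            continue
        indexes.append(vid)
        assigned.add(vid)
        chrom, pos = gwas.at[vid, "chrom"], gwas.at[vid, "pos"]
        near = gwas.index[
            (gwas["chrom"] == chrom)
            & (np.abs(gwas["pos"] - pos) <= kb * 1000)
            & ~gwas.index.isin(assigned)
        ]
        if len(near) == 0 or sd[vid] == 0:
            continue
        r = D[near].corrwith(D[vid])
        assigned.update(near[(r**2).to_numpy() > r2])
    return indexes


def gene_score(
    g: GenotypeMatrix,
    gwas: pd.DataFrame,
    index_variants: list[str],
    gene_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene weighted allele scores over the index variants.

    score[participant, gene] = sum over the gene's index variants of
    effect-allele dosage x GWAS beta. Genes whose variants were all clumped
    away simply have no column.
    """
    if gene_map is None:
        gene_map = g.variant_info["gene"]
    scores: dict[str, np.ndarray] = {}
    for vid in index_variants:
        gene = gene_map[vid]
        contrib = g.dosages[vid].to_numpy() * gwas.at[vid, "beta"]
        scores[gene] = scores.get(gene, 0.0) + contrib
    return pd.DataFrame(scores, index=g.participant_ids)


def stratified_correlation_test(
    profile: np.ndarray,
    symptoms: np.ndarray,
    score: np.ndarray,
    split: str = "median",
):
    """Fisher-z comparison of the profile-symptom correlation across gene-score strata.

    Participants are split at the score median ("median", default) or into
    outer tertiles ("tertile"); z = (atanh r_low - atanh r_high) /
    sqrt(1/(n_low-3) + 1/(n_high-3)) with a two-sided normal p.
    Returns (r_low, r_high, z, p).
    """
    profile, symptoms, score = (np.asarray(a, dtype=float) for a in (profile, symptoms, score))
    if split == "median":
        cut = np.median(score)
        low = score <= cut
        high = ~low
    elif split == "tertile":
        lo_cut, hi_cut = np.quantile(score, [1 / 3, 2 / 3])
        low = score <= lo_cut
        high = score >= hi_cut
    else:
        raise ValueError(f"unknown split rule: {split}")
    if low.sum() < 10 or high.sum() < 10:
        raise ValueError("each stratum needs at least 10 participants")
    r_low = float(np.corrcoef(profile[low], symptoms[low])[0, 1])
    r_high = float(np.corrcoef(profile[high], symptoms[high])[0, 1])
    if abs(r_low) >= 1 or abs(r_high) >= 1:
        raise ValueError("degenerate stratum correlation")
    z = (np.arctanh(r_low) - np.arctanh(r_high)) / np.sqrt(1 / (low.sum() - 3) + 1 / (high.sum() - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return r_low, r_high, float(z), p
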