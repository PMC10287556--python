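"""Synthetic multi-view cohort generator with known planted structure.

The generator emulates the data layout of a large population-cohort study of
urban living environments and mental health: an environment view (raw items
that collapse into latent categories), a symptom view, regional brain
volumes, biallelic genotype dosages in LD blocks, and confounding covariates
(age, sex, assessment center, batch, ancestry PCs, intracranial volume).

Planted structure, all recorded in :class:`SimTruth`:

* ``n_modes`` sparse canonical modes shared between environment categories
  and symptoms.  Mode *k* draws a latent pair (t_x, t_y) with correlation
  r_k; the support columns of each view are high-fidelity noisy indicators
  of their view's latent, so the population canonical correlation of the
  mode is approximately r_k (attenuated by ~1-2% indicator noise).
* Raw environment items are one-factor indicators of their category, so a
  confirmatory factor analysis stage has a true latent to recover.
* A brain mediator M on the path from the first environmental profile to a
  symptom outcome, moderated on both paths by a gene score W built from
  designated moderator genes (the "Model 59" pathway).
* Additive linear confound effects on every view, so linear residualization
  removes them exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import FeatureTable, GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_views",
    "simulate_genotypes",
    "simulate_moderated_mediation",
    "write_dataset",
]

#: loading of a raw environment item on its latent category
CFA_LOADING = 0.8


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_participants: int = 5000
    n_env_raw: int = 128
    n_env_categories: int = 53
    n_single_item_categories: int = 34
    n_symptoms: int = 21
    n_brain: int = 139
    mode_strengths: tuple = (0.3, 0.15)
    support_sizes: tuple = ((8, 6), (6, 5))  # per mode: (env, symptom) support
    n_snps: int = 60
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 10
    # imputed cohort data shows tight LD within blocks; 0.95 latent
    # autocorrelation yields adjacent dosage r2 ~ 0.6-0.8
    ld_rho: float = 0.95
    # (a1, a3, b1, b2, c', c3) of the moderated-mediation generator
    mediation_coefs: tuple = (0.5, 0.2, 0.4, 0.1, 0.2, 0.0)
    # additive main effect of the moderator gene score on the symptom
    # outcome, so the GWAS -> clump -> gene-score chain has a signal to find
    w_main_effect: float = 0.3
    n_moderator_genes: int = 1
    confound_effect_scale: float = 0.2
    # loading of a support column on its mode latent (signal sd per unit
    # noise sd); high values concentrate the cross-covariance, low values
    # spread it (the regime where the L1 sparsity bound is active)
    indicator_fidelity: float = 1.5
    # calibrate each mode's latent pair so the realized sample correlation
    # equals r_k exactly (the mvrnorm(empirical=TRUE) convention); the
    # planted value is then well-defined for the generated cohort
    exact_mode_correlation: bool = True
    continuous_dosage: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.support_sizes) != len(self.mode_strengths):
            raise ValueError("support_sizes must have one (env, sym) pair per mode")
        rs = list(self.mode_strengths)
        if any(not (0 < r < 1) for r in rs):
            raise ValueError("mode strengths must lie in (0, 1)")
        if rs != sorted(rs, reverse=True) or len(set(rs)) != len(rs):
            raise ValueError("mode_strengths must be strictly decreasing")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if sum(s for s, _ in self.support_sizes) > self.n_env_categories:
            raise ValueError("environment supports exceed n_env_categories")
        if sum(s for _, s in self.support_sizes) > self.n_symptoms:
            raise ValueError("symptom supports exceed n_symptoms")
        if self.confound_effect_scale < 0:
            raise ValueError("confound_effect_scale must be >= 0")

    @property
    def n_modes(self) -> int:
        return len(self.mode_strengths)


@dataclass
class SimTruth:
    """Planted ground truth serialized alongside the data."""

    planted_r: list
    planted_weights_env: list  # per mode, length n_env_categories
    planted_weights_sym: list
    mediation_coefs: tuple
    moderator_gene_ids: list
    category_members: dict  # category name -> raw item names
    latents_env: np.ndarray = field(repr=False, default=None)  # n x K
    latents_sym: np.ndarray = field(repr=False, default=None)
    mediator: np.ndarray = field(repr=False, default=None)
    gene_score: np.ndarray = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "planted_r": list(self.planted_r),
            "planted_weights_env": [list(map(float, w)) for w in self.planted_weights_env],
            "planted_weights_sym": [list(map(float, w)) for w in self.planted_weights_sym],
            "mediation_coefs": list(self.mediation_coefs),
            "moderator_gene_ids": list(self.moderator_gene_ids),
            "category_members": self.category_members,
        }


@dataclass
class SimDataset:
    env: FeatureTable            # category-level environment (what sCCA consumes)
    env_raw: FeatureTable        # raw items feeding the CFA stage
    symptoms: FeatureTable
    brain: FeatureTable
    genotypes: GenotypeMatrix
    covariates: FeatureTable
    mediation_outcome: FeatureTable  # single-column X/M/Y table for mediation


def _mode_supports(config: SimConfig, rng: np.random.Generator):
    """Disjoint per-view support index sets, drawn once."""
    env_pool = rng.permutation(config.n_env_categories)
    sym_pool = rng.permutation(config.n_symptoms)
    env_supports, sym_supports = [], []
    ei = si = 0
    for s_env, s_sym in config.support_sizes:
        env_supports.append(np.sort(env_pool[ei : ei + s_env]))
        sym_supports.append(np.sort(sym_pool[si : si + s_sym]))
        ei += s_env
        si += s_sym
    return env_supports, sym_supports


def _indicator_block(
    latent: np.ndarray, n_cols: int, rng: np.random.Generator, lam: float
) -> np.ndarray:
    noise = rng.standard_normal((latent.shape[0], n_cols))
    return (lam * latent[:, None] + noise) / np.hypot(lam, 1.0)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Dosages in AR(ld_rho) LD blocks, thresholded from latent Gaussians.

    Two independent latent haplotype chains per participant and block are
    thresholded at the allele-frequency quantile, so adjacent variants show
    the tetrachoric-induced dosage correlation of real LD.
    """
    if config.n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, m = config.n_participants, config.n_snps
    rho, bs = config.ld_rho, config.ld_block_size
    if not (0 <= rho < 1):
        raise ValueError("ld_rho must lie in [0, 1)")
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    def _haplotype_chain() -> np.ndarray:
        z = np.empty((n, m))
        for j in range(m):
            if j % bs == 0:
                z[:, j] = rng.standard_normal(n)
            else:
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        return z

    thr = norm.ppf(mafs)
    alleles1 = (_haplotype_chain() < thr).astype(float)
    alleles2 = (_haplotype_chain() < thr).astype(float)
    dos = alleles1 + alleles2
    if config.continuous_dosage:
        dos = np.clip(dos + rng.normal(0.0, 0.05, size=dos.shape), 0.0, 2.0)

    variant_ids = [f"rs{j + 1:05d}" for j in range(m)]
    block = np.arange(m) // bs
    info = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(m) * 5000 + 1,  # blocks contiguous, 1-based
            "effect_allele": "A",
            "other_allele": "G",
            "gene": [f"GENE{b + 1}" for b in block],
            "maf": np.minimum(dos.mean(axis=0) / 2, 1 - dos.mean(axis=0) / 2),
            "info": 1.0,
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    ids = pd.Index([f"P{i + 1:06d}" for i in range(n)], name="participant_id")
    return GenotypeMatrix(pd.DataFrame(dos, index=ids, columns=variant_ids), info)


def simulate_moderated_mediation(
    config: SimConfig,
    env_profile: np.ndarray,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator | None = None,
):
    """Generate mediator and outcome on a genotype-moderated pathway.

    M = a1*X + a3*X*W + e_M and
    Y = c'*X + c3*X*W + b1*M + b2*M*W + g*W + e_Y,
    where W is the standardized moderator-gene score (unweighted dosage sum
    over variants of the moderator genes), g = ``w_main_effect`` anchors a
    marginal genetic association detectable by GWAS, and noise is standard
    normal.

    Returns
    -------
    (mediator, outcome, gene_score) arrays of length ``n_participants``.
    """
    x = np.asarray(env_profile, dtype=float)
    if x.shape[0] != genotypes.dosages.shape[0]:
        raise ValueError("env_profile length must match the genotype cohort")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    a1, a3, b1, b2, c_prime, c3 = config.mediation_coefs
    genes = list(dict.fromkeys(genotypes.variant_info["gene"]))[: config.n_moderator_genes]
    keep = genotypes.variant_info["gene"].isin(genes).to_numpy()
    raw = genotypes.dosages.to_numpy()[:, keep].sum(axis=1)
    w = (raw - raw.mean()) / raw.std()
    x = (x - x.mean()) / x.std()
    m = a1 * x + a3 * x * w + rng.standard_normal(x.shape[0])
    y = (
        c_prime * x + c3 * x * w + b1 * m + b2 * m * w
        + config.w_main_effect * w
        + rng.standard_normal(x.shape[0])
    )
    return m, y, w


def simulate_views(config: SimConfig):
    """Generate the full multi-view cohort and its ground truth.

    Returns ``(SimDataset, SimTruth)``; bit-identical for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    n, K = config.n_participants, config.n_modes
    ids = pd.Index([f"P{i + 1:06d}" for i in range(n)], name="participant_id")

    env_supports, sym_supports = _mode_supports(config, rng)

    # mode latent pairs with corr r_k
    t_env = np.empty((n, K)) if K else np.empty((n, 0))
    t_sym = np.empty((n, K)) if K else np.empty((n, 0))
    for k, r in enumerate(config.mode_strengths):
        z0 = rng.standard_normal(n)
        z1 = rng.standard_normal(n)
        if config.exact_mode_correlation:
            z0 = (z0 - z0.mean()) / z0.std()
            z1 = z1 - z1.mean()
            z1 -= (z1 @ z0 / (z0 @ z0)) * z0  # exact sample orthogonality
            z1 /= z1.std()
        t_env[:, k] = z0
        t_sym[:, k] = r * z0 + np.sqrt(1 - r**2) * z1

    env_cat = rng.standard_normal((n, config.n_env_categories))
    sym = rng.standard_normal((n, config.n_symptoms))
    w_env, w_sym = [], []
    for k in range(K):
        lam = config.indicator_fidelity
        env_cat[:, env_supports[k]] = _indicator_block(t_env[:, k], len(env_supports[k]), rng, lam)
        sym[:, sym_supports[k]] = _indicator_block(t_sym[:, k], len(sym_supports[k]), rng, lam)
        we = np.zeros(config.n_env_categories)
        we[env_supports[k]] = 1 / np.sqrt(len(env_supports[k]))
        ws = np.zeros(config.n_symptoms)
        ws[sym_supports[k]] = 1 / np.sqrt(len(sym_supports[k]))
        w_env.append(we)
        w_sym.append(ws)

    # raw environment items: one-factor indicators of the multi-item categories
    cat_names = [f"env_cat{j + 1:02d}" for j in range(config.n_env_categories)]
    n_multi = config.n_env_categories - config.n_single_item_categories
    n_extra = config.n_env_raw - config.n_single_item_categories
    members_per_cat = np.full(n_multi, n_extra // n_multi)
    members_per_cat[: n_extra % n_multi] += 1
    raw_cols, raw_names, category_members = [], [], {}
    for j in range(config.n_single_item_categories):
        name = f"item_{cat_names[j]}"
        raw_cols.append(env_cat[:, j])
        raw_names.append(name)
        category_members[cat_names[j]] = [name]
    for idx, j in enumerate(range(config.n_single_item_categories, config.n_env_categories)):
        names = [f"item_{cat_names[j]}_{t + 1}" for t in range(members_per_cat[idx])]
        lam = CFA_LOADING
        for name in names:
            raw_cols.append(lam * env_cat[:, j] + np.sqrt(1 - lam**2) * rng.standard_normal(n))
            raw_names.append(name)
        category_members[cat_names[j]] = names

    genotypes = simulate_genotypes(config, rng)

    # moderated mediation chain off the first mode's environment latent
    x_profile = t_env[:, 0] if K else rng.standard_normal(n)
    mediator, outcome, gene_score = simulate_moderated_mediation(config, x_profile, genotypes, rng)
    m_std = (mediator - mediator.mean()) / mediator.std()
    brain = rng.standard_normal((n, config.n_brain))
    n_brain_sig = max(5, config.n_brain // 10)
    brain[:, :n_brain_sig] = _indicator_block(m_std, n_brain_sig, rng, 3.0)

    # covariates: age, sex, center, batch, 10 ancestry PCs, ICV
    cov = pd.DataFrame(index=ids)
    cov["age"] = rng.normal(59.0, 8.0, n)
    cov["sex"] = rng.integers(0, 2, n).astype(float)
    cov["center"] = rng.integers(0, 5, n).astype(float)
    cov["batch"] = rng.integers(0, 3, n).astype(float)
    for p in range(10):
        cov[f"pc{p + 1}"] = rng.standard_normal(n)
    cov["icv"] = rng.normal(1500.0, 120.0, n)

    # additive linear confound effects on all views
    scale = config.confound_effect_scale
    conf = np.column_stack(
        [
            (cov["age"] - cov["age"].mean()) / cov["age"].std(),
            cov["sex"] - cov["sex"].mean(),
            (cov["center"] - cov["center"].mean()) / max(cov["center"].std(), 1e-12),
        ]
    )

    def _add_confounds(mat: np.ndarray) -> np.ndarray:
        betas = rng.normal(0.0, scale, size=(conf.shape[1], mat.shape[1]))
        return mat + conf @ betas

    env_cat = _add_confounds(env_cat)
    raw = _add_confounds(np.column_stack(raw_cols))
    sym = _add_confounds(sym)
    brain = _add_confounds(brain)

    dataset = SimDataset(
        env=FeatureTable(pd.DataFrame(env_cat, index=ids, columns=cat_names), "environment"),
        env_raw=FeatureTable(pd.DataFrame(raw, index=ids, columns=raw_names), "environment_raw"),
        symptoms=FeatureTable(
            pd.DataFrame(sym, index=ids, columns=[f"symptom{j + 1:02d}" for j in range(config.n_symptoms)]),
            "symptoms",
        ),
        brain=FeatureTable(
            pd.DataFrame(brain, index=ids, columns=[f"roi{j + 1:03d}" for j in range(config.n_brain)]),
            "brain",
        ),
        genotypes=genotypes,
        covariates=FeatureTable(cov, "covariates"),
        mediation_outcome=FeatureTable(
            pd.DataFrame(
                {"env_profile": x_profile, "brain_component": mediator, "symptom_group": outcome},
                index=ids,
            ),
            "mediation",
        ),
    )
    genes = list(dict.fromkeys(genotypes.variant_info["gene"]))[: config.n_moderator_genes]
    truth = SimTruth(
        planted_r=list(config.mode_strengths),
        planted_weights_env=w_env,
        planted_weights_sym=w_sym,
        mediation_coefs=config.mediation_coefs,
        moderator_gene_ids=genes,
        category_members=category_members,
        latents_env=t_env,
        latents_sym=t_sym,
        mediator=mediator,
        gene_score=gene_score,
    )
    return dataset, truth


def write_dataset(dataset: SimDataset, truth: SimTruth, outdir: str | Path) -> None:
    """Write the cohort as TSV tables plus truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in [
        ("env", dataset.env),
        ("env_raw", dataset.env_raw),
        ("symptoms", dataset.symptoms),
        ("brain", dataset.brain),
        ("covariates", dataset.covariates),
        ("mediation", dataset.mediation_outcome),
    ]:
        table.data.to_csv(out / f"{name}.tsv", sep="\t")
    dataset.genotypes.dosages.to_csv(out / "genotypes.tsv", sep="\t")
    dataset.genotypes.variant_info.to_csv(out / "variants.tsv", sep="\t")
    (out / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=1))
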