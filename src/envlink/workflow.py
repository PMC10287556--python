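"""End-to-end orchestration: simulate/load -> QC -> sCCA -> GWAS -> msCCA -> mediation.

``full_pipeline`` replays the whole analysis chain on one cohort with the
same split bookkeeping as the original design: the non-imaging subset
carries the environment-symptom sparse CCA and the GWAS of its symptom
variates; the imaging subset carries the three-block msCCA and the
moderated-mediation analysis. Every stage's seed derives from the single
run seed by a fixed counter scheme, and a manifest records config hash,
per-stage seeds, output hashes and timings so deterministic stages can be
verified bit-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .cfa import LatentCategorySpec, build_categories
from .datatypes import FeatureTable
from .genetics import clump, gene_score, gwas_linear, qc_variants, stratified_correlation_test
from .mediation import Model59Spec, bootstrap_bca_ci
from .mscca import run_mscca_pipeline
from .pipeline import PipelineConfig, crossloadings_ev_fev, run_multi_mode, split_train_test
from .preprocess import mad_filter, near_zero_variance, residualize
from .synthetic import SimConfig, simulate_views, write_dataset

__all__ = ["RunConfig", "full_pipeline"]


@dataclass
class RunConfig:
    outdir: str = "envlink_run"
    sim: SimConfig | None = None       # simulate when set ...
    data_dir: str | None = None        # ... otherwise load TSVs from here
    seed: int = 0
    mad_k: float = 4.0
    use_cfa_categories: bool = False   # score env categories from raw items by CV-CFA
    imaging_fraction: float = 0.4
    scca: PipelineConfig = field(default_factory=lambda: PipelineConfig(n_resamples=50, n_perm=99, max_modes=3))
    mscca: PipelineConfig = field(
        default_factory=lambda: PipelineConfig(
            n_resamples=30, n_perm=49, stability_threshold=0.85, max_modes=1
        )
    )
    mscca_enabled: bool = True
    mediation_enabled: bool = True
    mediation_B: int = 499

    def stage_seed(self, k: int) -> int:
        return (self.seed * 100003 + 7919 * k + 1) % (2**31)


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.round(12).to_csv().encode()).hexdigest()[:16]


def _std_cols(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (M - M.mean(axis=0)) / sd


def full_pipeline(config: RunConfig) -> dict:
    """Run every stage on one cohort; returns the manifest dict.

    Raises before any computation if the configuration cannot support the
    enabled stages.
    """
    out = Path(config.outdir)
    # -- validation up front
    if config.sim is None and config.data_dir is None:
        raise ValueError("either sim or data_dir must be set")
    if config.data_dir is not None:
        d = Path(config.data_dir)
        needed = ["env.tsv", "symptoms.tsv", "covariates.tsv", "genotypes.tsv", "variants.tsv"]
        if config.mscca_enabled:
            needed.append("brain.tsv")
        missing = [f for f in needed if not (d / f).exists()]
        if missing:
            raise FileNotFoundError(f"data_dir lacks required tables: {missing}")
    out.mkdir(parents=True, exist_ok=True)

    cfg_dict = asdict(config)
    cfg_dict.pop("outdir")  # a location, not a computational parameter
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stage_seeds": {},
        "timings": {},
        "output_hashes": {},
        "warnings": [],
    }
    t0 = time.time()

    # -- stage 1: obtain the cohort
    if config.sim is not None:
        dataset, truth = simulate_views(config.sim)
        write_dataset(dataset, truth, out / "data")
        env_raw, env, symptoms = dataset.env_raw, dataset.env, dataset.symptoms
        brain, genotypes, covariates = dataset.brain, dataset.genotypes, dataset.covariates
        category_members = truth.category_members
    else:
        d = Path(config.data_dir)
        env = eio.read_feature_table(d / "env.tsv", view_label="environment")
        env_raw = (
            eio.read_feature_table(d / "env_raw.tsv", view_label="environment_raw")
            if (d / "env_raw.tsv").exists()
            else None
        )
        symptoms = eio.read_feature_table(d / "symptoms.tsv", view_label="symptoms")
        brain = eio.read_feature_table(d / "brain.tsv", view_label="brain") if config.mscca_enabled else None
        genotypes = eio.read_dosages(d / "genotypes.tsv", variants_path=d / "variants.tsv")
        covariates = eio.read_feature_table(d / "covariates.tsv", view_label="covariates")
        category_members = None
        if (d / "truth.json").exists():
            category_members = json.loads((d / "truth.json").read_text()).get("category_members")
    manifest["timings"]["load"] = time.time() - t0

    # -- stage 2: QC + confound residualization
    t = time.time()
    env, qc_env = mad_filter(env, k=config.mad_k)
    symptoms, qc_sym = mad_filter(symptoms, k=config.mad_k)
    nzv = near_zero_variance(env)
    manifest["qc"] = {
        "env_masked": int(qc_env.masked_counts.sum()),
        "symptoms_masked": int(qc_sym.masked_counts.sum()),
        "nzv_flagged": int(nzv.nzv_flags["flagged"].sum()),
    }
    if config.use_cfa_categories:
        if env_raw is None or category_members is None:
            raise ValueError("CFA categories require env_raw.tsv and category membership")
        specs = [
            LatentCategorySpec(name, members) for name, members in category_members.items()
        ]
        env = build_categories(env_raw, specs, n_folds=10, seed=config.stage_seed(1))
    conf_cols = [c for c in ("age", "sex", "center") if c in covariates.feature_names]
    conf = covariates.select_features(conf_cols)
    env_r = residualize(env, conf, zscore=True)
    sym_r = residualize(symptoms, conf, zscore=True)
    ids = env_r.participant_ids.intersection(sym_r.participant_ids)
    env_r, sym_r = env_r.select_participants(ids), sym_r.select_participants(ids)
    manifest["timings"]["preprocess"] = time.time() - t

    # -- cohort masks: imaging subset mirrors a neuroimaging sub-study
    rng = np.random.default_rng(config.stage_seed(2))
    manifest["stage_seeds"]["cohort_split"] = config.stage_seed(2)
    n = len(ids)
    imaging_mask = np.zeros(n, dtype=bool)
    imaging_mask[rng.choice(n, size=int(round(config.imaging_fraction * n)), replace=False)] = True
    ids_nonimg, ids_img = ids[~imaging_mask], ids[imaging_mask]

    # -- stage 3: environment-symptom sparse CCA on the non-imaging subset
    t = time.time()
    scca_cfg = PipelineConfig(**{**asdict(config.scca), "seed": config.stage_seed(3)})
    manifest["stage_seeds"]["scca"] = scca_cfg.seed
    train_ids, test_ids = split_train_test(ids_nonimg, scca_cfg.train_fraction, scca_cfg.seed)
    Xtr = _std_cols(env_r.select_participants(train_ids).values)
    Ytr = _std_cols(sym_r.select_participants(train_ids).values)
    Xte = _std_cols(env_r.select_participants(test_ids).values)
    Yte = _std_cols(sym_r.select_participants(test_ids).values)
    scca_res = run_multi_mode(Xtr, Ytr, Xte, Yte, scca_cfg)
    modes_out = []
    for m in scca_res.modes:
        modes_out.append(
            {
                "mode": m.mode_index,
                "r_train": m.r_train,
                "p_perm_train": m.p_perm_train,
                "r_test": m.r_test,
                "p_perm_test": m.p_perm_test,
                "p_fdr": m.p_fdr,
                "stable_env": [env_r.feature_names[i] for i in m.stable_x],
                "stable_symptoms": [sym_r.feature_names[i] for i in m.stable_y],
            }
        )
    (out / "modes.json").write_text(json.dumps(modes_out, indent=1))
    if scca_res.modes:
        W = pd.DataFrame(
            {f"mode{m.mode_index}_env": m.w_x for m in scca_res.modes},
            index=env_r.feature_names,
        )
        W.to_csv(out / "weights_env.tsv", sep="\t")
        variates = np.column_stack([Ytr @ m.w_y for m in scca_res.modes])
        rho, ev, fev = crossloadings_ev_fev(Xtr, variates, [m.stable_x for m in scca_res.modes])
        pd.DataFrame(ev, index=env_r.feature_names).to_csv(out / "ev.tsv", sep="\t")
        pd.DataFrame(fev).to_csv(out / "fev.tsv", sep="\t")
        manifest["output_hashes"]["weights_env"] = _hash_df(W)
    manifest["scca"] = {"n_modes": scca_res.n_significant, "stopped": scca_res.stopped_reason}
    manifest["timings"]["scca"] = time.time() - t

    gene_scores = None
    top_gene = None
    if scca_res.modes:
        # -- stage 4: GWAS of the first symptom variate, clumping, gene scores
        t = time.time()
        gsub = genotypes.select_participants(ids_nonimg)
        gsub = qc_variants(gsub)
        y_variate = _std_cols(sym_r.select_participants(ids_nonimg).values) @ scca_res.modes[0].w_y
        gwas_cov = covariates.select_features(
            [c for c in covariates.feature_names if c.startswith("pc") or c in ("age", "sex", "center", "batch")]
        ).select_participants(ids_nonimg)
        gwas = gwas_linear(y_variate, gsub, gwas_cov)
        gwas.to_csv(out / "gwas.tsv", sep="\t")
        index_variants = clump(gwas, gsub)
        scores_nonimg = gene_score(gsub, gwas, index_variants)
        # moderation screen: stratified correlation comparison per gene
        x_variate = _std_cols(env_r.select_participants(ids_nonimg).values) @ scca_res.modes[0].w_x
        strat = {}
        for gene in scores_nonimg.columns:
            r_lo, r_hi, z, p = stratified_correlation_test(
                x_variate, y_variate, scores_nonimg[gene].to_numpy()
            )
            strat[gene] = {"r_low": r_lo, "r_high": r_hi, "z": z, "p": p}
        (out / "gene_moderation.json").write_text(json.dumps(strat, indent=1))
        top_gene = min(strat, key=lambda g: strat[g]["p"])
        gene_scores = gene_score(genotypes.select_variants(gsub.variant_ids), gwas, index_variants)
        gene_scores.to_csv(out / "gene_scores.tsv", sep="\t")
        manifest["gwas"] = {
            "n_variants": int(len(gwas)),
            "n_index": len(index_variants),
            "top_gene": top_gene,
            "top_gene_z": strat[top_gene]["z"],
        }
        manifest["output_hashes"]["gwas"] = _hash_df(gwas)
        manifest["timings"]["gwas"] = time.time() - t

    mscca_res = None
    if config.mscca_enabled and scca_res.modes:
        # -- stage 5: three-block msCCA on the imaging subset
        t = time.time()
        conf_icv_cols = conf_cols + (["icv"] if "icv" in covariates.feature_names else [])
        brain_r = residualize(brain, covariates.select_features(conf_icv_cols), zscore=True)
        img_ids = ids_img.intersection(brain_r.participant_ids)
        mscca_cfg = PipelineConfig(**{**asdict(config.mscca), "seed": config.stage_seed(5)})
        manifest["stage_seeds"]["mscca"] = mscca_cfg.seed
        tr_i, te_i = split_train_test(img_ids, mscca_cfg.train_fraction, mscca_cfg.seed)
        blocks_tr = [
            _std_cols(env_r.select_participants(tr_i).values),
            _std_cols(brain_r.select_participants(tr_i).values),
            _std_cols(sym_r.select_participants(tr_i).values),
        ]
        blocks_te = [
            _std_cols(env_r.select_participants(te_i).values),
            _std_cols(brain_r.select_participants(te_i).values),
            _std_cols(sym_r.select_participants(te_i).values),
        ]
        mscca_res = run_mscca_pipeline(*blocks_tr, *blocks_te, config=mscca_cfg)
        pairs = []
        for m in mscca_res.modes:
            pairs.append(
                {
                    "mode": m.mode_index,
                    **{f"r_train_{a}_{b}": v for (a, b), v in m.pairwise_r_train.items()},
                    **{f"r_test_{a}_{b}": v for (a, b), v in m.pairwise_r_test.items()},
                    "p_perm": m.objective_p_perm,
                }
            )
        pd.DataFrame(pairs).to_csv(out / "pairwise_r.tsv", sep="\t", index=False)
        manifest["mscca"] = {"n_modes": len(mscca_res.modes), "stopped": mscca_res.stopped_reason}
        manifest["timings"]["mscca"] = time.time() - t

    if config.mediation_enabled and scca_res.modes and gene_scores is not None and mscca_res and mscca_res.modes:
        # -- stage 6: moderated mediation on the imaging subset
        t = time.time()
        med_ids = tr_i
        x = _std_cols(env_r.select_participants(med_ids).values) @ scca_res.modes[0].w_x
        mvar = _std_cols(brain_r.select_participants(med_ids).values) @ mscca_res.modes[0].weights[1]
        yvar = _std_cols(sym_r.select_participants(med_ids).values) @ scca_res.modes[0].w_y
        wscore = gene_scores.loc[med_ids, top_gene].to_numpy()
        med_df = pd.DataFrame({"x": x, "m": mvar, "y": yvar, "w": wscore})
        spec = Model59Spec(x="x", m="m", y="y", w="w", B=config.mediation_B, seed=config.stage_seed(6))
        manifest["stage_seeds"]["mediation"] = spec.seed
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            med = bootstrap_bca_ci(med_df, spec)
        med_out = {
            "gene": top_gene,
            "coefficients": {**{k: float(v) for k, v in med.fit.a.items()},
                             **{k: float(v) for k, v in med.fit.b.items()}},
            "effects": med.effects.reset_index().to_dict(orient="records"),
            "eme_percent": med.eme_percent,
        }
        (out / "mediation.json").write_text(json.dumps(med_out, indent=1, default=float))
        manifest["mediation"] = {"eme_percent": med.eme_percent, "gene": top_gene}
        manifest["timings"]["mediation"] = time.time() - t

    manifest["output_hashes"]["modes"] = hashlib.sha256((out / "modes.json").read_bytes()).hexdigest()[:16]
    manifest["timings"]["total"] = time.time() - t0
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
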