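"""Dosage GWAS, LD clumping, gene scores, stratified moderation test."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from envlink import (
    FeatureTable,
    GenotypeMatrix,
    SimConfig,
    bonferroni_threshold,
    clump,
    gene_score,
    gwas_linear,
    ld_r2,
    qc_variants,
    simulate_genotypes,
    simulate_moderated_mediation,
    stratified_correlation_test,
)


def toy_genotypes(dosages, pos=None, chrom=None, maf=None, info=None, genes=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    vids = [f"v{j}" for j in range(m)]
    vinfo = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
            "effect_allele": "A",
            "other_allele": "G",
            "gene": genes if genes is not None else ["G1"] * m,
            "maf": maf if maf is not None else dosages.mean(axis=0) / 2,
            "info": info if info is not None else 1.0,
        },
        index=pd.Index(vids, name="variant_id"),
    )
    dos = pd.DataFrame(dosages, index=[f"P{i}" for i in range(n)], columns=vids)
    return GenotypeMatrix(dos, vinfo)


class TestQc:
    def test_clean_set_untouched(self, rng):
        g = toy_genotypes(rng.integers(0, 3, (20, 5)).astype(float), maf=[0.25] * 5)
        assert qc_variants(g).n_variants == 5

    def test_rare_variant_dropped(self, rng):
        g = toy_genotypes(rng.integers(0, 3, (20, 3)).astype(float), maf=[0.25, 0.0005, 0.3])
        out = qc_variants(g)
        assert list(out.variant_ids) == ["v0", "v2"]

    def test_mixed_failures_counted(self, rng):
        maf = [0.3] * 7 + [0.0001, 0.0002, 0.3]
        info = [1.0] * 9 + [0.1]
        g = toy_genotypes(rng.integers(0, 3, (30, 10)).astype(float), maf=maf, info=info)
        assert qc_variants(g).n_variants == 7


class TestGwas:
    def test_effect_size_recovered(self, rng):
        n = 20000
        dose = rng.binomial(2, 0.3, n).astype(float)
        y = 0.2 * dose + rng.standard_normal(n)
        g = toy_genotypes(dose[:, None])
        tab = gwas_linear(y, g)
        assert 0.18 <= tab["beta"].iloc[0] <= 0.22
        assert tab["p"].iloc[0] < 1e-10

    def test_null_pvalues_uniform(self, rng):
        n, m = 10000, 1000
        G = rng.binomial(2, 0.3, (n, m)).astype(float)
        y = rng.standard_normal(n)
        tab = gwas_linear(y, toy_genotypes(G))
        from scipy.stats import kstest

        assert kstest(tab["p"], "uniform").pvalue > 0.01

    def test_matches_statsmodels_ols(self, rng):
        n = 500
        G = rng.binomial(2, 0.4, (n, 20)).astype(float)
        cov = FeatureTable(
            pd.DataFrame(
                {"age": rng.standard_normal(n), "sex": rng.integers(0, 2, n)},
                index=[f"P{i}" for i in range(n)],
            )
        )
        y = rng.standard_normal(n)
        tab = gwas_linear(y, toy_genotypes(G), cov)
        for j in range(20):
            Z = sm.add_constant(np.column_stack([G[:, j], cov.values]))
            ref = sm.OLS(y, Z).fit()
            assert tab["beta"].iloc[j] == pytest.approx(ref.params[1], abs=1e-8)
            assert tab["se"].iloc[j] == pytest.approx(ref.bse[1], abs=1e-8)
            assert tab["p"].iloc[j] == pytest.approx(ref.pvalues[1], abs=1e-8)

    def test_collinear_covariates_rejected(self, rng):
        n = 100
        c = rng.standard_normal(n)
        cov = FeatureTable(pd.DataFrame({"a": c, "b": 2 * c}, index=[f"P{i}" for i in range(n)]))
        g = toy_genotypes(rng.binomial(2, 0.3, (n, 2)).astype(float))
        with pytest.raises(ValueError, match="collinear"):
            gwas_linear(rng.standard_normal(n), g, cov)


def test_bonferroni_arithmetic():
    assert bonferroni_threshold(100, 1) == pytest.approx(5e-4)
    assert bonferroni_threshold(13_918_727, 3) == pytest.approx(0.05 / 41_756_181)
    assert bonferroni_threshold(1, 1) == 0.05


class TestLdR2:
    def test_self_correlation_is_one(self, rng):
        g = toy_genotypes(rng.binomial(2, 0.4, (200, 2)).astype(float))
        assert ld_r2(g, "v0", "v0") == pytest.approx(1.0)

    def test_duplicated_column_is_one(self, rng):
        d = rng.binomial(2, 0.4, 200).astype(float)
        g = toy_genotypes(np.column_stack([d, d]))
        assert ld_r2(g, "v0", "v1") == pytest.approx(1.0)

    def test_independent_variants_near_zero(self, rng):
        G = rng.binomial(2, 0.3, (100000, 2)).astype(float)
        g = toy_genotypes(G)
        assert ld_r2(g, "v0", "v1") < 0.001

    def test_monomorphic_rejected(self):
        g = toy_genotypes(np.column_stack([np.ones(50), np.zeros(50)]))
        with pytest.raises(ValueError, match="zero-variance"):
            ld_r2(g, "v0", "v1")


def clump_oracle_check(gwas, g, indexes, r2=0.5, kb=250.0):
    """Verifier: every removed variant is linked to an earlier index; every
    retained pair of indexes violates at least one gate."""
    removed = set(gwas.index) - set(indexes)
    order = {v: i for i, v in enumerate(indexes)}
    for v in removed:
        linked = False
        for idx in indexes:
            same_chrom = gwas.at[v, "chrom"] == gwas.at[idx, "chrom"]
            near = abs(gwas.at[v, "pos"] - gwas.at[idx, "pos"]) <= kb * 1000
            if same_chrom and near and ld_r2(g, v, idx) > r2:
                if gwas.at[idx, "p"] <= gwas.at[v, "p"]:
                    linked = True
                    break
        if not linked:
            return False
    for a in indexes:
        for b in indexes:
            if a >= b:
                continue
            same = gwas.at[a, "chrom"] == gwas.at[b, "chrom"]
            near = abs(gwas.at[a, "pos"] - gwas.at[b, "pos"]) <= kb * 1000
            if same and near and ld_r2(g, a, b) > r2:
                return False
    return True


class TestClump:
    def test_tight_ld_block_single_index(self, rng):
        base = rng.binomial(2, 0.4, 2000).astype(float)
        G = np.column_stack([base, base, base]).astype(float)
        # tiny perturbation keeps r2 ~ 1
        G[:5, 1] = 2 - G[:5, 1]
        g = toy_genotypes(G, pos=[100, 200, 300])
        gwas = pd.DataFrame(
            {"chrom": "1", "pos": [100, 200, 300], "p": [0.01, 0.5, 0.2]}, index=g.variant_ids
        )
        assert clump(gwas, g) == ["v0"]

    def test_distance_gate_keeps_distant_duplicates(self, rng):
        base = rng.binomial(2, 0.4, 2000).astype(float)
        g = toy_genotypes(np.column_stack([base, base]), pos=[1, 300_001])
        gwas = pd.DataFrame({"chrom": "1", "pos": [1, 300_001], "p": [0.01, 0.2]}, index=g.variant_ids)
        assert set(clump(gwas, g, kb=250)) == {"v0", "v1"}

    def test_random_instances_satisfy_constraint_oracle(self, rng):
        for trial in range(60):
            m = int(rng.integers(3, 15))
            cfg = SimConfig(
                n_participants=300, n_snps=m, ld_block_size=int(rng.integers(2, 6)),
                ld_rho=float(rng.uniform(0, 0.95)), seed=int(rng.integers(1e6)),
            )
            g = simulate_genotypes(cfg)
            gw = pd.DataFrame(
                {"chrom": g.variant_info["chrom"], "pos": g.variant_info["pos"],
                 "p": rng.uniform(size=m)},
                index=g.variant_ids,
            )
            kb = float(rng.choice([5, 10, 250]))
            idx = clump(gw, g, r2=0.5, kb=kb)
            assert clump_oracle_check(gw, g, idx, r2=0.5, kb=kb)


class TestGeneScore:
    def test_single_variant_arithmetic(self):
        g = toy_genotypes(np.array([[2.0]]))
        gwas = pd.DataFrame({"beta": [0.5]}, index=g.variant_ids)
        s = gene_score(g, gwas, ["v0"])
        assert s.iloc[0, 0] == pytest.approx(1.0)

    def test_two_variant_hand_computation(self):
        g = toy_genotypes(np.array([[2.0, 1.0]]))
        gwas = pd.DataFrame({"beta": [0.5, -0.2]}, index=g.variant_ids)
        s = gene_score(g, gwas, ["v0", "v1"])
        assert s.iloc[0, 0] == pytest.approx(0.8)

    def test_linearity_in_betas(self, rng):
        G = rng.binomial(2, 0.3, (50, 4)).astype(float)
        g = toy_genotypes(G, genes=["G1", "G1", "G2", "G2"])
        gwas = pd.DataFrame({"beta": rng.standard_normal(4)}, index=g.variant_ids)
        s1 = gene_score(g, gwas, list(g.variant_ids))
        s2 = gene_score(g, gwas.assign(beta=2 * gwas["beta"]), list(g.variant_ids))
        assert np.allclose(s2.to_numpy(), 2 * s1.to_numpy())

    def test_zero_betas_zero_scores(self, rng):
        G = rng.binomial(2, 0.3, (20, 3)).astype(float)
        g = toy_genotypes(G)
        gwas = pd.DataFrame({"beta": [0.0] * 3}, index=g.variant_ids)
        assert (gene_score(g, gwas, list(g.variant_ids)) == 0).all().all()


class TestStratifiedCorrelation:
    def _exact_corr_pair(self, rng, n, r):
        """Two vectors whose sample correlation is exactly r."""
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= (e @ x / (x @ x)) * x
        e /= e.std()
        return x, r * x + np.sqrt(1 - r**2) * e

    def test_identical_strata_z_zero(self, rng):
        x, y = self._exact_corr_pair(rng, 50, 0.3)
        profile = np.concatenate([x, x])
        sym = np.concatenate([y, y])
        score = np.concatenate([np.zeros(50), np.ones(50)])
        r_lo, r_hi, z, p = stratified_correlation_test(profile, sym, score)
        assert z == pytest.approx(0.0, abs=1e-10) and p == pytest.approx(1.0)

    def test_hand_evaluated_fisher_z(self, rng):
        x1, y1 = self._exact_corr_pair(rng, 50, 0.1)
        x2, y2 = self._exact_corr_pair(rng, 50, 0.5)
        profile = np.concatenate([x1, x2])
        sym = np.concatenate([y1, y2])
        score = np.concatenate([np.zeros(50), np.ones(50)])
        _, _, z, _ = stratified_correlation_test(profile, sym, score)
        expected = (np.arctanh(0.1) - np.arctanh(0.5)) / np.sqrt(2 / 47)
        assert z == pytest.approx(expected, abs=1e-6)
        assert z == pytest.approx(-2.18, abs=0.01)

    def test_planted_moderation_detected(self):
        cfg = SimConfig(
            n_participants=20000, n_snps=10,
            mediation_coefs=(0.5, 0.2, 0.4, 0.0, 0.2, 0.0), seed=77,
        )
        g = simulate_genotypes(cfg)
        rng = np.random.default_rng(78)
        x = rng.standard_normal(20000)
        m, y, w = simulate_moderated_mediation(cfg, x, g)
        _, _, z, p = stratified_correlation_test(x, y, w)
        assert z < 0 and p < 0.01
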