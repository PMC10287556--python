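"""One-factor CFA: ML recovery, fit indices, pruning, out-of-fold scoring."""

import numpy as np
import pandas as pd
import pytest

from envlink import (
    FeatureTable,
    LatentCategorySpec,
    build_categories,
    cfa_item_prune,
    cfa_scores,
    fit_cfa_one_factor,
    indices_from_chi2,
)


def one_factor_data(n, loadings, rng):
    f = rng.standard_normal(n)
    lam = np.asarray(loadings)
    X = f[:, None] * lam + rng.standard_normal((n, len(lam))) * np.sqrt(1 - lam**2)
    return FeatureTable(pd.DataFrame(X, columns=[f"it{j}" for j in range(len(lam))])), f


class TestFit:
    def test_loading_recovery(self, rng):
        items, _ = one_factor_data(20000, [0.7] * 5, rng)
        model = fit_cfa_one_factor(items)
        assert np.all(np.abs(model.loadings - 0.7) < 0.02)
        assert np.all(model.uniquenesses > 0)

    def test_exact_covariance_gives_zero_chi2(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        psi = 1 - lam**2
        S = np.outer(lam, lam) + np.diag(psi)
        model = fit_cfa_one_factor(S=S, n=1000)
        assert model.fit["chi2"] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(np.abs(model.loadings), lam, atol=1e-4)

    def test_independent_items_loadings_near_zero(self, rng):
        items = FeatureTable(pd.DataFrame(rng.standard_normal((5000, 4)), columns=list("abcd")))
        model = fit_cfa_one_factor(items)
        assert np.abs(model.loadings).max() < 0.2

    def test_sign_convention_sum_nonnegative(self, rng):
        items, _ = one_factor_data(2000, [0.7, 0.6, 0.5], rng)
        flipped = FeatureTable(-items.data)
        assert fit_cfa_one_factor(flipped).loadings.sum() >= 0

    def test_too_few_items_rejected(self, rng):
        items, _ = one_factor_data(100, [0.7, 0.6], rng)
        with pytest.raises(ValueError, match=">= 3 items"):
            fit_cfa_one_factor(items)


class TestFitIndices:
    def test_hand_evaluated_formulas(self):
        idx = indices_from_chi2(chi2=100, df=5, chi2_b=1000, df_b=10, n=1001)
        assert idx["cfi"] == pytest.approx(1 - 95 / 990, abs=1e-12)
        assert idx["rmsea"] == pytest.approx(np.sqrt(95 / 5000), abs=1e-12)
        assert idx["tli"] == pytest.approx((100 - 20) / (100 - 1), abs=1e-12)

    def test_chi2_equal_df_gives_zero_rmsea(self):
        assert indices_from_chi2(5, 5, 100, 10, 500)["rmsea"] == 0.0

    def test_perfect_fit_gives_unit_cfi(self):
        idx = indices_from_chi2(0, 5, 100, 10, 500)
        assert idx["cfi"] == 1.0

    def test_df_zero_rejected(self):
        with pytest.raises(ValueError):
            indices_from_chi2(1, 0, 10, 5, 100)


class TestPrune:
    def test_well_fitting_battery_untouched(self, rng):
        items, _ = one_factor_data(5000, [0.8, 0.7, 0.7, 0.6, 0.6], rng)
        model = cfa_item_prune(items)
        assert len(model.item_names) == 5 and len(model.pruning_trail) == 1

    def test_structure_violating_item_removed(self, rng):
        """An item correlated with one indicator's uniqueness (not the factor)
        breaks the one-factor structure and is pruned first."""
        items, _ = one_factor_data(20000, [0.7] * 5, rng)
        bad = 0.45 * items.data["it0"] + np.sqrt(1 - 0.45**2) * rng.standard_normal(20000)
        df = items.data.assign(bad=bad)
        model = cfa_item_prune(FeatureTable(df))
        assert "bad" not in model.item_names and len(model.item_names) == 5

    def test_unfittable_battery_raises_with_trail(self, rng):
        n = 5000
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        X = np.column_stack(
            [0.9 * f1 + 0.3 * rng.standard_normal(n),
             0.9 * f1 + 0.3 * rng.standard_normal(n),
             0.9 * f2 + 0.3 * rng.standard_normal(n)]
        )
        # two strong pairwise structures cannot satisfy one factor at 3 items...
        items = FeatureTable(pd.DataFrame(X, columns=list("abc")))
        try:
            model = cfa_item_prune(items, min_items=3)
        except RuntimeError as err:
            assert hasattr(err, "best_model") and len(err.trail) == 1
        else:
            # ...unless the third item decouples; then nothing is pruned
            assert len(model.item_names) == 3


class TestScores:
    def test_zero_vector_scores_zero(self):
        lam = np.array([0.8, 0.7, 0.6])
        S = np.outer(lam, lam) + np.diag(1 - lam**2)
        model = fit_cfa_one_factor(S=S, n=500, item_names=["a", "b", "c"])
        new = FeatureTable(pd.DataFrame([model.item_means], columns=["a", "b", "c"]))
        assert cfa_scores(model, new).iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_dominant_item_limit(self):
        """With lambda = e1 and a tiny first uniqueness, the regression score
        collapses to the first item's centered value."""
        from envlink.cfa import CfaModel

        model = CfaModel(
            item_names=["a", "b", "c"],
            loadings=np.array([1.0, 0.0, 0.0]),
            uniquenesses=np.array([1e-6, 1.0, 1.0]),
            item_means=np.zeros(3),
            fit={}, n_fit=500, converged=True, gradient_norm=0.0,
        )
        x = pd.DataFrame([[2.0, 5.0, -3.0]], columns=["a", "b", "c"])
        score = cfa_scores(model, FeatureTable(x)).iloc[0]
        assert score == pytest.approx(2.0, abs=1e-3)

    def test_scores_recover_generating_latent(self, rng):
        items, f = one_factor_data(20000, [0.85] * 5, rng)
        model = fit_cfa_one_factor(items)
        scores = cfa_scores(model, items)
        assert abs(np.corrcoef(scores, f)[0, 1]) > 0.95

    def test_column_mismatch_rejected(self, rng):
        items, _ = one_factor_data(500, [0.7] * 3, rng)
        model = fit_cfa_one_factor(items)
        with pytest.raises(ValueError, match="columns"):
            cfa_scores(model, items.select_features(["it1", "it0", "it2"]))


class TestBuildCategories:
    def test_single_item_specs_copied_through(self, rng):
        raw = FeatureTable(pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"]))
        specs = [LatentCategorySpec("A", ["a"]), LatentCategorySpec("B", ["b"])]
        out = build_categories(raw, specs, n_folds=2)
        assert np.array_equal(out.data[["A", "B"]].to_numpy(), raw.data[["a", "b"]].to_numpy())

    def test_out_of_fold_scores_recover_latent(self, rng):
        items, f = one_factor_data(20000, [0.8] * 5, rng)
        specs = [LatentCategorySpec("cat", list(items.feature_names))]
        out = build_categories(items, specs, n_folds=10, seed=1)
        assert abs(np.corrcoef(out.data["cat"], f)[0, 1]) > 0.9

    def test_fold_count_barely_matters(self, rng):
        items, _ = one_factor_data(20000, [0.8] * 5, rng)
        specs = [LatentCategorySpec("cat", list(items.feature_names))]
        s2 = build_categories(items, specs, n_folds=2, seed=1).data["cat"]
        s10 = build_categories(items, specs, n_folds=10, seed=1).data["cat"]
        assert abs(np.corrcoef(s2, s10)[0, 1]) > 0.98

    def test_specs_must_partition_items(self, rng):
        raw = FeatureTable(pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"]))
        with pytest.raises(ValueError, match="partition"):
            build_categories(raw, [LatentCategorySpec("A", ["a"])])
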