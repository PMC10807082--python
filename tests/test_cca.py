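import numpy as np
import pandas as pd
import pytest

from latentconn.cca import (
    CCAConfig,
    analyze,
    association_feature_modes,
    explained_variance,
    ev_profile,
    fit_cca,
    select_components,
)
from latentconn.synthetic import plant_behavior


class TestFitCCA:
    def test_identical_single_columns_correlation_one(self):
        x = np.arange(10.0).reshape(-1, 1)
        fit = fit_cca(x, x.copy())
        assert fit.corrs[0] == pytest.approx(1.0)

    def test_independent_views_near_zero(self):
        rng = np.random.default_rng(0)
        X, Y = rng.standard_normal((2000, 4)), rng.standard_normal((2000, 4))
        assert fit_cca(X, Y).corrs[0] < 0.1

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 30))
        behavior, _ = plant_behavior(X, [0.8], noise_sd=1.0, seed=2)
        fit = fit_cca(X, behavior.to_numpy())
        assert abs(fit.corrs[0] - 0.8) < 0.1
        # chance level for 30-dim X vs 4-dim Y at n=300 is ~sqrt(34/300)
        assert fit.corrs[1] < 0.45

    def test_correlations_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 8))
        Y = rng.standard_normal((100, 4)) + 0.3 * X[:, :4]
        fit = fit_cca(X, Y)
        assert (np.diff(fit.corrs) <= 1e-12).all()

    def test_variates_orthogonal_within_view(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 6))
        Y = rng.standard_normal((200, 4)) + 0.5 * X[:, :4]
        fit = fit_cca(X, Y)
        u, v = fit.transform(X, Y)
        uc = (u - u.mean(0)).T @ (u - u.mean(0))
        vc = (v - v.mean(0)).T @ (v - v.mean(0))
        assert np.allclose(uc - np.diag(np.diag(uc)), 0, atol=1e-8)
        assert np.allclose(vc - np.diag(np.diag(vc)), 0, atol=1e-8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((150, 5))
        Y = rng.standard_normal((150, 4)) + 0.4 * X[:, :4]
        A = rng.standard_normal((5, 5)) + 3 * np.eye(5)
        B = rng.standard_normal((4, 4)) + 3 * np.eye(4)
        base = fit_cca(X, Y).corrs
        trans = fit_cca(X @ A + 1.0, Y @ B - 2.0).corrs
        assert np.allclose(base, trans, atol=1e-8)

    def test_matches_sklearn_cca(self):
        # independent NIPALS implementation as cross-check oracle
        from sklearn.cross_decomposition import CCA as SkCCA

        rng = np.random.default_rng(6)
        X = rng.standard_normal((120, 6))
        Y = rng.standard_normal((120, 4)) + 0.6 * X[:, :4]
        ours = fit_cca(X, Y, CCAConfig(max_components=2)).corrs
        sk = SkCCA(n_components=2, max_iter=2000).fit(X, Y)
        u, v = sk.transform(X, Y)
        sk_corrs = [abs(np.corrcoef(u[:, c], v[:, c])[0, 1]) for c in range(2)]
        assert np.allclose(ours, sk_corrs, atol=1e-3)

    def test_singular_view_raises_helpful_error(self):
        X = np.ones((20, 3))  # zero variance after centering
        Y = np.random.default_rng(7).standard_normal((20, 4))
        with pytest.raises(np.linalg.LinAlgError, match="reduce"):
            fit_cca(X, Y)

    def test_wide_x_reduced_by_pca(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 500))
        Y = rng.standard_normal((40, 4))
        fit = fit_cca(X, Y)
        assert fit.pca_components is not None
        assert fit.pca_components.shape[0] <= 20  # min(n // 2, 50)
        assert fit.x_weights_full().shape[0] == 500


class TestSelectComponents:
    def test_two_planted_components_selected(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((500, 30))
        behavior, _ = plant_behavior(X, [0.9, 0.85], noise_sd=1.0, seed=10)
        sel, table = select_components(X, behavior.to_numpy(), CCAConfig(seed=11))
        assert sel == 2
        assert set(table["fold"]) == set(range(5))

    def test_null_selects_zero(self):
        rng = np.random.default_rng(12)
        X, Y = rng.standard_normal((300, 20)), rng.standard_normal((300, 4))
        sel, _ = select_components(X, Y, CCAConfig(seed=13, n_perm=500))
        assert sel == 0

    def test_folds_partition_all_rows(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((50, 6))
        Y = rng.standard_normal((50, 4))
        _, table = select_components(X, Y, CCAConfig(seed=15, n_perm=100))
        # each fold contributes max_components rows
        assert len(table) == 5 * 4

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            select_components(np.zeros((8, 2)), np.zeros((8, 2)), CCAConfig())


class TestExplainedVariance:
    def test_perfect_prediction(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert explained_variance(x, x) == 1.0

    def test_mean_prediction_zero(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert explained_variance(x, np.full(4, x.mean())) == 0.0

    def test_worked_example_matches_brute_force(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        x_hat = np.array([1.0, 2.0, 3.0, 8.0])
        # brute force with population variances: 1 - Var{x - x_hat}/Var{x}
        expected = 1.0 - np.var(x - x_hat) / np.var(x)
        assert expected == pytest.approx(-1.4)
        assert explained_variance(x, x_hat) == pytest.approx(expected)

    def test_constant_x_undefined(self):
        assert np.isnan(explained_variance(np.ones(5), np.zeros(5)))


class TestEvProfile:
    def _planted(self, seed=16):
        rng = np.random.default_rng(seed)
        n, d = 200, 20
        X = rng.standard_normal((n, d))
        behavior, _ = plant_behavior(X, [0.9], noise_sd=1.0, seed=seed + 1)
        return X, behavior.to_numpy()

    def test_zero_selected_components_zero_ev(self):
        X, Y = self._planted()
        fit = fit_cca(X, Y)
        ev_scores, ev_feat, _ = ev_profile(X, Y, fit, selected=0)
        assert (ev_scores == 0).all() and (ev_feat == 0).all()

    def test_score_ev_bounded_by_one(self):
        X, Y = self._planted()
        fit = fit_cca(X, Y)
        ev_scores, _, _ = ev_profile(X, Y, fit, selected=2)
        assert (ev_scores <= 1 + 1e-12).all()

    def test_block_with_planted_loadings_attains_max_ev(self):
        rng = np.random.default_rng(17)
        n, d = 300, 24
        X = rng.standard_normal((n, d))
        # load behavior only on the first 6 features = one network block
        w = np.zeros(d)
        w[:6] = rng.standard_normal(6)
        t = X @ w
        t /= t.std()
        Y = 2.0 * np.outer(t, np.ones(4)) + rng.standard_normal((n, 4))
        nets = np.array(
            [("visual", "visual")] * 6 + [("limbic", "limbic")] * 18, dtype=object
        )
        fit = fit_cca(X, Y)
        _, ev_feat, block = ev_profile(X, Y, fit, selected=1, edge_networks=nets)
        assert block.loc["visual", "visual"] == np.nanmax(block.to_numpy())


class TestAssociationFeatureModes:
    def test_identical_features_identical_results(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((60, 10))
        behavior, _ = plant_behavior(
            X, [0.8], seed=19, subject_ids=[f"s{i}" for i in range(60)]
        )
        cfg = CCAConfig(seed=20, n_perm=200)
        results, comparison = association_feature_modes(
            {"a": X, "b": X.copy()}, behavior, cfg
        )
        ta = results["a"].component_table["heldout_r"]
        tb = results["b"].component_table["heldout_r"]
        assert np.allclose(ta, tb)

    def test_generating_mode_beats_independent_mode(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((200, 15))
        behavior, _ = plant_behavior(
            X, [0.85], seed=22, subject_ids=[f"s{i}" for i in range(200)]
        )
        other = rng.standard_normal((200, 15))
        cfg = CCAConfig(seed=23, n_perm=300)
        _, comparison = association_feature_modes(
            {"attributions": X, "noise": other}, behavior, cfg
        )
        first = comparison[comparison["component"] == 0].set_index("mode")
        assert (
            first.loc["attributions", "mean_heldout_r"]
            > first.loc["noise", "mean_heldout_r"]
        )

    def test_missing_scores_dropped(self, caplog):
        rng = np.random.default_rng(24)
        X = rng.standard_normal((60, 8))
        behavior, _ = plant_behavior(
            X, [0.8], seed=25, subject_ids=[f"s{i}" for i in range(60)]
        )
        behavior.loc[:9, "ados_total"] = np.nan
        import logging

        with caplog.at_level(logging.INFO, logger="latentconn.cca"):
            association_feature_modes({"a": X}, behavior, CCAConfig(seed=26, n_perm=100))
        assert "dropping 10 subjects" in caplog.text
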