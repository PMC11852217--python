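import numpy as np
import pytest

from swinegp.bayeslin import fit_gblup
from swinegp.containers import GRMatrix
from swinegp.grm import vanraden_grm
from swinegp.mlpred import (
    EnsembleConfig,
    fit_adaboost_r2,
    fit_gbdt,
    fit_krr,
    fit_krr_rbf,
    fit_rf,
    fit_tree,
    make_features,
    predict_krr,
    weighted_median,
)
from swinegp.pheno import standardize


class TestFeatures:
    def test_toy_grm_rows_by_direct_indexing(self):
        vals = np.arange(25, dtype=float).reshape(5, 5)
        vals = (vals + vals.T) / 2
        G = GRMatrix(vals, [f"i{k}" for k in range(5)])
        fv = make_features(G, train_ids=["i0", "i2"], query_ids=["i3", "i1"])
        assert np.allclose(fv.matrix, vals[np.ix_([3, 1], [0, 2])])

    def test_query_equals_train_gives_train_block(self):
        vals = np.eye(4) + 0.1
        G = GRMatrix(vals, list("abcd"))
        fv = make_features(G, list("abcd"), list("abcd"))
        assert np.allclose(fv.matrix, vals)

    def test_permuting_train_ids_permutes_columns(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 6))
        vals = vals @ vals.T
        G = GRMatrix(vals, [f"i{k}" for k in range(6)])
        a = make_features(G, ["i0", "i1", "i2"], ["i4", "i5"]).matrix
        b = make_features(G, ["i2", "i0", "i1"], ["i4", "i5"]).matrix
        assert np.allclose(a[:, [2, 0, 1]], b)

    def test_unknown_id_raises(self):
        G = GRMatrix(np.eye(3), list("abc"))
        with pytest.raises(KeyError):
            make_features(G, ["a", "z"], ["b"])


class TestKrr:
    def test_identity_kernel_closed_form(self):
        y = np.arange(5.0)
        model = fit_krr(np.eye(5), y, lam=1.0)
        # test sample identical to training sample j: k' = e_j -> y_j / 2
        assert predict_krr(model, np.eye(5)[3])[0] == pytest.approx(y[3] / 2)

    def test_vanishing_ridge_interpolates(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(20, 20))
        K = A @ A.T + 20 * np.eye(20)
        y = rng.normal(size=20)
        model = fit_krr(K, y, lam=1e-12)
        assert np.allclose(predict_krr(model, K), y, atol=1e-6)

    def test_matches_direct_linear_solve(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(20, 20))
        K = A @ A.T
        y = rng.normal(size=20)
        lam = 0.7
        model = fit_krr(K, y, lam)
        direct = K[:5] @ np.linalg.solve(K + lam * np.eye(20), y)
        assert np.allclose(predict_krr(model, K[:5]), direct, atol=1e-10)

    def test_non_psd_kernel_rejected(self):
        K = np.diag([1.0, -1.0, 1.0])
        with pytest.raises(ValueError, match="PSD"):
            fit_krr(K, np.ones(3), lam=0.1)
        with pytest.raises(ValueError):
            fit_krr(np.eye(3), np.ones(3), lam=0.0)

    def test_rbf_mode_reference_oracle(self):
        sklearn = pytest.importorskip("sklearn.kernel_ridge")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        model = fit_krr_rbf(X, y, lam=0.5, gamma=0.3)
        ref = sklearn.KernelRidge(alpha=0.5, kernel="rbf", gamma=0.3).fit(X, y)
        assert np.allclose(predict_krr(model, X), ref.predict(X), atol=1e-8)

    def test_gblup_ranking_reproduced_by_linear_krr(self, herd):
        from scipy.stats import spearmanr

        _, geno, table, _ = herd
        y = standardize(table.data["trait"].to_numpy())
        G = vanraden_grm(geno)
        fit = fit_gblup(G, y, varcomp=(0.5, 0.5))
        krr = fit_krr(G.values, y - fit.mu, lam=1.0)
        rho = spearmanr(predict_krr(krr, G.values), fit.gebv).statistic
        assert rho == pytest.approx(1.0)


class TestTree:
    def test_constant_target_gives_root_leaf(self):
        X = np.random.default_rng(4).normal(size=(20, 3))
        t = fit_tree(X, np.full(20, 3.5), EnsembleConfig(min_samples_leaf=1))
        assert t.root.is_leaf and t.root.value == pytest.approx(3.5)

    def test_step_function_split_at_boundary(self):
        X = np.linspace(0, 1, 50)[:, None]
        y = (X[:, 0] > 0.5).astype(float)
        t = fit_tree(X, y, EnsembleConfig(max_depth=1, min_samples_leaf=1))
        assert t.root.threshold == pytest.approx(0.5, abs=0.02)
        assert t.root.left.value == 0.0 and t.root.right.value == 1.0

    def test_deeper_trees_never_increase_training_mse(self, small_xy):
        X, y = small_xy
        mses = [
            np.mean(
                (fit_tree(X, y, EnsembleConfig(max_depth=d, min_samples_leaf=1)).predict(X) - y)
                ** 2
            )
            for d in range(1, 7)
        ]
        assert np.all(np.diff(mses) <= 1e-12)

    def test_matches_sklearn_cart_oracle(self, small_xy):
        DecisionTreeRegressor = pytest.importorskip(
            "sklearn.tree"
        ).DecisionTreeRegressor
        X, y = small_xy
        ours = fit_tree(X, y, EnsembleConfig(max_depth=4, min_samples_leaf=5))
        ref = DecisionTreeRegressor(max_depth=4, min_samples_leaf=5).fit(X, y)
        assert np.allclose(ours.predict(X), ref.predict(X), atol=1e-12)

    def test_histogram_mode_close_to_exact(self, small_xy):
        X, y = small_xy
        exact = fit_tree(X, y, EnsembleConfig(max_depth=3, min_samples_leaf=5))
        hist = fit_tree(
            X, y, EnsembleConfig(max_depth=3, min_samples_leaf=5, histogram_bins=64)
        )
        r = np.corrcoef(exact.predict(X), hist.predict(X))[0, 1]
        assert r > 0.95


class TestForest:
    def test_single_tree_reduction(self, small_xy):
        X, y = small_xy
        cfg = EnsembleConfig(
            n_estimators=1, subsample=1.0, feature_fraction=1.0,
            max_depth=3, min_samples_leaf=5, seed=1,
        )
        rf = fit_rf(X, y, cfg)
        tree = fit_tree(X, y, cfg, rng=np.random.default_rng(1))
        assert np.allclose(rf.predict(X), tree.predict(X))

    def test_prediction_is_mean_of_member_trees(self, small_xy):
        X, y = small_xy
        rf = fit_rf(X, y, EnsembleConfig(n_estimators=7, max_depth=3, seed=2))
        stacked = np.mean([t.predict(X) for t in rf.trees], axis=0)
        assert np.allclose(rf.predict(X), stacked)

    def test_bagging_beats_single_tree_out_of_sample(self):
        # Friedman-style nonlinear regression surface
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(300, 5))
        f = (
            10 * np.sin(np.pi * X[:, 0] * X[:, 1])
            + 20 * (X[:, 2] - 0.5) ** 2
            + 10 * X[:, 3]
            + 5 * X[:, 4]
        )
        y = f + rng.standard_normal(300)
        tr, te = np.arange(200), np.arange(200, 300)
        cfg = EnsembleConfig(n_estimators=60, max_depth=6, min_samples_leaf=3,
                             feature_fraction=0.6, seed=3)
        rf = fit_rf(X[tr], y[tr], cfg)
        tree = fit_tree(X[tr], y[tr], EnsembleConfig(max_depth=6, min_samples_leaf=3))
        mse_rf = np.mean((rf.predict(X[te]) - y[te]) ** 2)
        mse_tree = np.mean((tree.predict(X[te]) - y[te]) ** 2)
        assert mse_rf < mse_tree

    def test_seed_reproducibility(self, small_xy):
        X, y = small_xy
        cfg = EnsembleConfig(n_estimators=5, max_depth=3, seed=9)
        assert np.array_equal(fit_rf(X, y, cfg).predict(X), fit_rf(X, y, cfg).predict(X))


class TestGbdt:
    def test_zero_stages_predict_the_mean(self, small_xy):
        X, y = small_xy
        model = fit_gbdt(X, y, EnsembleConfig(n_estimators=0))
        assert np.allclose(model.predict(X), y.mean())

    def test_single_stump_full_rate_fits_step_exactly(self):
        X = np.repeat([[0.0], [1.0]], 10, axis=0)
        y = np.repeat([2.0, 6.0], 10)
        model = fit_gbdt(
            X, y, EnsembleConfig(n_estimators=1, learning_rate=1.0, max_depth=1,
                                 min_samples_leaf=1),
        )
        assert np.allclose(model.predict(X), y)

    def test_training_mse_non_increasing(self, small_xy):
        X, y = small_xy
        model = fit_gbdt(
            X, y, EnsembleConfig(n_estimators=40, learning_rate=0.3, max_depth=3,
                                 min_samples_leaf=5),
        )
        assert np.all(np.diff(model.staged_train_mse(X, y)) <= 1e-9)

    def test_goss_keep_all_is_bitwise_plain_gbdt(self, small_xy):
        X, y = small_xy
        base = dict(n_estimators=15, max_depth=3, min_samples_leaf=5, seed=4)
        plain = fit_gbdt(X, y, EnsembleConfig(**base))
        goss = fit_gbdt(X, y, EnsembleConfig(**base, goss_top=1.0, goss_rest=0.2))
        assert np.array_equal(plain.predict(X), goss.predict(X))

    def test_goss_subsampling_still_learns(self, small_xy):
        X, y = small_xy
        model = fit_gbdt(
            X, y, EnsembleConfig(n_estimators=40, learning_rate=0.3, max_depth=3,
                                 min_samples_leaf=5, goss_top=0.3, goss_rest=0.3,
                                 seed=5),
        )
        assert np.corrcoef(model.predict(X), y)[0, 1] > 0.8


class TestAdaboostR2:
    def test_single_learner_equals_its_output(self, small_xy):
        X, y = small_xy
        model = fit_adaboost_r2(
            X, y, EnsembleConfig(n_estimators=1, max_depth=3, min_samples_leaf=5, seed=6)
        )
        assert np.allclose(model.predict(X), model.learners[0].predict(X))

    def test_weighted_median_inequality_form(self):
        # weights {1.0, 0.1}: the first carries >= half the total weight
        assert weighted_median(np.array([[2.0], [7.0]]), np.array([1.0, 0.1]))[0] == 2.0
        # equal weights, even count: infimum picks the lower middle value
        assert weighted_median(
            np.array([[1.0], [3.0], [5.0], [9.0]]), np.ones(4)
        )[0] == 3.0

    def test_identical_learners_are_degenerate_median(self):
        X = np.zeros((10, 1))
        y = np.full(10, 4.2)
        model = fit_adaboost_r2(X, y, EnsembleConfig(n_estimators=3, seed=7))
        assert np.allclose(model.predict(X), 4.2)

    def test_boosting_improves_over_rounds(self, small_xy):
        X, y = small_xy
        weak = fit_adaboost_r2(X, y, EnsembleConfig(n_estimators=1, max_depth=2, seed=8))
        strong = fit_adaboost_r2(X, y, EnsembleConfig(n_estimators=25, max_depth=2, seed=8))
        mse_w = np.mean((weak.predict(X) - y) ** 2)
        mse_s = np.mean((strong.predict(X) - y) ** 2)
        assert mse_s < mse_w


def test_all_regressors_beat_chance_on_grm_features(herd):
    """On the sparse-QTL herd, every regressor predicts with r > 0 and none
    beats the noise ceiling sqrt(h2)."""
    cfg, geno, table, truth = herd
    y = standardize(table.data["trait"].to_numpy())
    G = vanraden_grm(geno)
    tr, te = np.arange(200), np.arange(200, 250)
    Xtr = G.values[np.ix_(tr, tr)]
    Xte = G.values[np.ix_(te, tr)]
    ceiling = np.sqrt(truth.realized_h2) + 0.12  # finite-sample slack
    ecfg = EnsembleConfig(n_estimators=60, max_depth=4, min_samples_leaf=5,
                          feature_fraction=0.5, seed=10, histogram_bins=32)
    models = {
        "krr": predict_krr(fit_krr(Xtr, y[tr], lam=1.0), Xte),
        "rf": fit_rf(Xtr, y[tr], ecfg).predict(Xte),
        "gbdt": fit_gbdt(Xtr, y[tr], ecfg).predict(Xte),
        "lgb": fit_gbdt(
            Xtr, y[tr],
            EnsembleConfig(n_estimators=60, max_depth=4, min_samples_leaf=5,
                           goss_top=0.3, goss_rest=0.3, seed=10, histogram_bins=32),
        ).predict(Xte),
        "ada": fit_adaboost_r2(Xtr, y[tr], ecfg).predict(Xte),
    }
    for name, pred in models.items():
        r = np.corrcoef(pred, y[te])[0, 1]
        assert 0.0 < r < ceiling, (name, r)
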