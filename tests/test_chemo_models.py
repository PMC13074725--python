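import numpy as np
import pytest

from nirmtl.chemo_models import (cross_val_rmse_plsr, fit_plsda, fit_plsr,
                                 fit_svr_grid, select_lvs_mccv)


class TestPlsr:
    def test_rank_one_exact(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(0, 1, 30), np.zeros(30)])
        y = 2.0 * X[:, 0]
        model = fit_plsr(X, y, 1)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-9)

    def test_full_lvs_match_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (40, 6))
        y = rng.normal(0, 1, 40)
        model = fit_plsr(X, y, 6)
        Xd = np.column_stack([np.ones(40), X])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), Xd @ beta, atol=1e-6)

    def test_invalid_lv_counts(self):
        X = np.random.default_rng(2).normal(0, 1, (10, 4))
        y = X[:, 0]
        with pytest.raises(ValueError):
            fit_plsr(X, y, 0)
        with pytest.raises(ValueError):
            fit_plsr(X, y, 11)


class TestMccvSelection:
    def test_planted_rank_recovered(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, (80, 2))
        loadings = rng.normal(0, 1, (2, 15))
        X = scores @ loadings + rng.normal(0, 0.01, (80, 15))
        y = scores @ [1.0, -2.0]
        n_lv, press = select_lvs_mccv(X, y, max_lv=8, n_splits=30, seed=0)
        assert n_lv == 2
        assert press[1] < press[0]

    def test_pure_noise_prefers_few_lvs(self):
        picks = []
        for seed in range(7):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (40, 10))
            y = rng.normal(0, 1, 40)
            picks.append(select_lvs_mccv(X, y, max_lv=8, n_splits=20,
                                         seed=seed)[0])
        assert np.median(picks) <= 3

    def test_zero_splits_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (20, 5))
        with pytest.raises(ValueError, match="n_splits"):
            select_lvs_mccv(X, X[:, 0], n_splits=0)


class TestPlsda:
    def test_separable_clusters(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.3, (20, 4)),
                       rng.normal(5, 0.3, (20, 4))])
        labels = np.array(["craft"] * 20 + ["industrial"] * 20,
                          dtype=object)
        model = fit_plsda(X, labels, 2)
        assert np.mean(model.predict(X) == labels) == 1.0

    def test_three_class_round_trip(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [6, 0], [0, 6]], dtype=float)
        X = np.vstack([c + rng.normal(0, 0.2, (15, 2)) for c in centers])
        labels = np.array(sum(([c] * 15 for c in
                               ("craft", "industrial", "non_fermented")),
                              []), dtype=object)
        model = fit_plsda(X, labels, 2)
        assert np.array_equal(model.predict(X), labels)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.3, (15, 3)),
                       rng.normal(4, 0.3, (15, 3))])
        labels = np.array(["craft"] * 15 + ["non_fermented"] * 15,
                          dtype=object)
        swapped = np.where(labels == "craft", "non_fermented",
                           "craft").astype(object)
        pred = fit_plsda(X, labels, 2).predict(X)
        pred_swapped = fit_plsda(X, swapped, 2).predict(X)
        assert np.array_equal(
            pred_swapped,
            np.where(pred == "craft", "non_fermented", "craft"))

    def test_argmax_tie_takes_lowest_class(self):
        model = fit_plsda(np.array([[0.0], [1.0], [0.0], [1.0]]),
                          np.array(["craft", "industrial"] * 2,
                                   dtype=object), 1)
        model.coef = np.zeros_like(model.coef)     # force exact ties
        model.y_mean = np.zeros_like(model.y_mean)
        assert list(model.predict(np.array([[3.0]]))) == ["craft"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_plsda(np.zeros((5, 2)), ["craft"] * 5, 1)


class TestSvrGrid:
    def test_single_point_grid(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (30, 3))
        y = X @ [1.0, 0.5, -0.2]
        grid = {"C": (10.0,), "gamma": (0.1,), "epsilon": (0.01,)}
        model = fit_svr_grid(X, y, grid, k=5, seed=0)
        assert (model.C, model.gamma) == (10.0, 0.1)

    def test_grid_matches_bruteforce_cv_oracle(self):
        from sklearn.model_selection import KFold
        from sklearn.svm import SVR

        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (36, 2))
        y = np.sin(X[:, 0]) + 0.2 * X[:, 1]
        grid = {"C": (1.0, 10.0), "gamma": (0.1, 1.0), "epsilon": (0.01,)}
        model = fit_svr_grid(X, y, grid, k=4, seed=3)

        x_mean, x_sd = X.mean(0), X.std(0, ddof=1)
        y_mean, y_sd = y.mean(), y.std(ddof=1)
        Xs, ys = (X - x_mean) / x_sd, (y - y_mean) / y_sd
        oracle = {}
        for C in grid["C"]:
            for gamma in grid["gamma"]:
                sq = 0.0
                folds = KFold(4, shuffle=True, random_state=3).split(Xs)
                for tr, te in folds:
                    est = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=0.01)
                    est.fit(Xs[tr], ys[tr])
                    sq += np.sum((est.predict(Xs[te]) - ys[te]) ** 2)
                oracle[(C, gamma)] = np.sqrt(sq / len(ys))
        best = min(oracle, key=lambda k: (oracle[k], k))
        assert (model.C, model.gamma) == best
        assert model.cv_rmse == pytest.approx(oracle[best], rel=1e-10)

    def test_smooth_function_recovery(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(-2, 2, 120)[:, None]
        y = np.sin(1.5 * x[:, 0])
        model = fit_svr_grid(x[:80], y[:80], k=5, seed=0)
        pred = model.predict(x[80:])
        ss = 1 - np.sum((pred - y[80:]) ** 2) / np.sum(
            (y[80:] - y[80:].mean()) ** 2)
        assert ss > 0.99

    def test_reproducible_winner(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (30, 2))
        y = X[:, 0] ** 2
        a = fit_svr_grid(X, y, k=5, seed=11)
        b = fit_svr_grid(X, y, k=5, seed=11)
        assert (a.C, a.gamma, a.cv_rmse) == (b.C, b.gamma, b.cv_rmse)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            fit_svr_grid(np.zeros((10, 2)), np.zeros(10), {"C": ()})


def test_cross_val_rmse_decreases_with_signal():
    rng = np.random.default_rng(12)
    X = rng.normal(0, 1, (50, 8))
    y_signal = X @ rng.normal(0, 1, 8)
    y_noise = rng.normal(0, 1, 50)
    assert (cross_val_rmse_plsr(X, y_signal, 8, k=5)
            < cross_val_rmse_plsr(X, y_noise, 8, k=5))
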