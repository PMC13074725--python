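"""Downstream chemometric models: PLSR, PLS-DA and grid-searched SVR.

PLS fits are delegated to :class:`sklearn.cross_decomposition.PLSRegression`
(NIPALS) with mean-centering only; latent-variable (LV) counts are chosen by
Monte Carlo cross-validation (MCCV) under the minimum-PRESS criterion.
Discriminant analysis regresses a one-hot class matrix and predicts the
argmax column.  Support-vector regression uses an RBF kernel with penalty and
kernel width selected by exhaustive grid search under k-fold RMSECV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, ShuffleSplit, StratifiedKFold
from sklearn.svm import SVR

__all__ = [
    "PlsModel", "SvrModel", "fit_plsr", "fit_plsda", "select_lvs_mccv",
    "fit_svr_grid", "cross_val_rmse_plsr", "cross_val_error_rate_plsda",
]


def _feasible_lvs(n_lv: int, n_samples: int, n_features: int) -> int:
    return int(min(n_lv, n_features, n_samples - 1))


def _fit_centered_pls(X: np.ndarray, Y: np.ndarray, n_lv: int):
    """Center X and Y, fit NIPALS PLS, return (model, x_mean, y_mean).

    Constant X columns are tolerated (they carry no weight) and ``n_lv`` is
    capped at the effective rank of the centered matrix so NIPALS cannot
    deflate into a numerically empty subspace.
    """
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    rank = np.linalg.matrix_rank(Xc)
    if rank == 0:
        raise ValueError("X has zero variance")
    model = PLSRegression(n_components=int(min(n_lv, rank)), scale=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        model.fit(Xc, Y - y_mean)
    if not np.all(np.isfinite(model.coef_)):
        raise ValueError("PLS fit is numerically degenerate")
    return model, x_mean, y_mean


@dataclass
class PlsModel:
    """A fitted PLS regression or discriminant model."""

    n_lv: int
    mode: str                      # "regression" | "discriminant"
    coef: np.ndarray               # (p, q) regression coefficients
    x_mean: np.ndarray
    y_mean: np.ndarray
    classes: tuple = ()
    algorithm: str = "nipals"

    def predict_response(self, X: np.ndarray) -> np.ndarray:
        Y = (np.asarray(X, float) - self.x_mean) @ self.coef + self.y_mean
        return Y

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions: response values, or class labels in discriminant mode.

        Discriminant argmax ties resolve to the lowest class index.
        """
        Y = self.predict_response(X)
        if self.mode == "regression":
            return Y[:, 0] if Y.shape[1] == 1 else Y
        idx = np.argmax(Y, axis=1)  # np.argmax takes the first (lowest) tie
        return np.asarray([self.classes[i] for i in idx], dtype=object)


def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int) -> PlsModel:
    """Fit mean-centered PLS regression with ``n_lv`` latent variables."""
    X = np.asarray(X, float)
    Y = np.asarray(y, float).reshape(len(X), -1)
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n_lv > _feasible_lvs(n_lv, *X.shape):
        raise ValueError(f"n_lv={n_lv} exceeds data rank bound")
    model, x_mean, y_mean = _fit_centered_pls(X, Y, n_lv)
    return PlsModel(n_lv, "regression", model.coef_.T, x_mean, y_mean)


def fit_plsda(X: np.ndarray, class_labels, n_lv: int) -> PlsModel:
    """PLS-DA: PLS regression on a one-hot class matrix, argmax decision."""
    labels = np.asarray(class_labels, dtype=object)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    Y = np.stack([(labels == c).astype(float) for c in classes], axis=1)
    X = np.asarray(X, float)
    n_lv = _feasible_lvs(n_lv, *X.shape)
    model, x_mean, y_mean = _fit_centered_pls(X, Y, n_lv)
    return PlsModel(n_lv, "discriminant", model.coef_.T, x_mean, y_mean,
                    classes=classes)


def select_lvs_mccv(X: np.ndarray, y: np.ndarray, max_lv: int = 20,
                    n_splits: int = 100, holdout_fraction: float = 0.25,
                    seed: int = 0) -> tuple[int, np.ndarray]:
    """Choose the LV count by Monte Carlo CV under minimum mean PRESS.

    For each LV count 1..max_lv the predicted residual sum of squares on the
    random holdout is averaged over ``n_splits`` splits; ties break toward
    fewer LVs.  Returns ``(n_lv, press_curve)``.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    X = np.asarray(X, float)
    y = np.asarray(y, float).reshape(len(X), -1)
    n = len(X)
    n_hold = int(round(holdout_fraction * n))
    if n_hold < 1 or n - n_hold < 2:
        raise ValueError("holdout too small to evaluate")
    max_lv = _feasible_lvs(max_lv, n - n_hold, X.shape[1])
    press = np.zeros(max_lv)
    splitter = ShuffleSplit(n_splits=n_splits, test_size=n_hold,
                            random_state=seed)
    for train, hold in splitter.split(X):
        model, x_mean, y_mean = _fit_centered_pls(X[train], y[train], max_lv)
        # coefficient matrices for every truncated LV count from one fit:
        # B_k = W_k (P_k' W_k)^{-1} Q_k'
        W, P, Q = model.x_weights_, model.x_loadings_, model.y_loadings_
        Xc = X[hold] - x_mean
        for k in range(1, max_lv + 1):
            Bk = W[:, :k] @ np.linalg.solve(P[:, :k].T @ W[:, :k], Q[:, :k].T)
            resid = Xc @ Bk + y_mean - y[hold]
            press[k - 1] += float(np.sum(resid ** 2))
    press /= n_splits
    return int(np.argmin(press)) + 1, press


def _regression_folds(n: int, k: int, seed: int):
    return KFold(n_splits=k, shuffle=True, random_state=seed).split(
        np.empty(n))


def cross_val_rmse_plsr(X: np.ndarray, y: np.ndarray, n_lv: int,
                        k: int = 10, seed: int = 0) -> float:
    """Pooled k-fold RMSECV of a fixed-LV PLSR fit."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    sq_sum, count = 0.0, 0
    for train, test in _regression_folds(len(X), k, seed):
        lv = _feasible_lvs(n_lv, len(train), X.shape[1])
        model = fit_plsr(X[train], y[train], lv)
        resid = model.predict(X[test]) - y[test]
        sq_sum += float(np.sum(resid ** 2))
        count += len(test)
    return float(np.sqrt(sq_sum / count))


def cross_val_error_rate_plsda(X: np.ndarray, labels, n_lv: int,
                               k: int = 10, seed: int = 0) -> float:
    """Pooled k-fold cross-validated misclassification rate of PLS-DA."""
    X = np.asarray(X, float)
    labels = np.asarray(labels, dtype=object)
    errors, count = 0, 0
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train, test in folds.split(X, labels):
        if len(set(labels[train])) < 2:
            raise ValueError("fold with a single class")
        model = fit_plsda(X[train], labels[train], n_lv)
        pred = model.predict(X[test])
        errors += int(np.sum(pred != labels[test]))
        count += len(test)
    return errors / count


@dataclass
class SvrModel:
    """RBF support-vector regression on standardized features and target."""

    C: float
    gamma: float
    epsilon: float
    estimator: SVR
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    cv_rmse: float = np.nan
    grid_rmse: dict = field(default_factory=dict)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.x_mean) / self.x_sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(self._scale(X)) * self.y_sd + self.y_mean


DEFAULT_SVR_GRID = {
    "C": (0.1, 1.0, 10.0, 100.0, 1000.0),
    "gamma": (1e-3, 1e-2, 1e-1, 1.0, 10.0),
    "epsilon": (0.01,),
}


def fit_svr_grid(X: np.ndarray, y: np.ndarray, grid: dict | None = None,
                 k: int = 10, seed: int = 0) -> SvrModel:
    """Exhaustive (C, gamma, epsilon) grid search by k-fold RMSECV.

    Features and target are standardized on the full calibration statistics;
    the winning point (ties: smallest C, then smallest gamma) is refit on all
    data.  CV RMSE values are recorded per grid point for inspection.
    """
    grid = dict(DEFAULT_SVR_GRID if grid is None else grid)
    if not all(len(grid.get(key, ())) for key in ("C", "gamma", "epsilon")):
        raise ValueError("grid must list C, gamma and epsilon values")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1)) or 1.0
    Xs, ys = (X - x_mean) / x_sd, (y - y_mean) / y_sd

    folds = list(_regression_folds(len(X), min(k, len(X)), seed))
    results: dict[tuple, float] = {}
    for C in sorted(grid["C"]):
        for gamma in sorted(grid["gamma"]):
            for eps in sorted(grid["epsilon"]):
                sq, count = 0.0, 0
                for train, test in folds:
                    est = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=eps)
                    est.fit(Xs[train], ys[train])
                    resid = est.predict(Xs[test]) - ys[test]
                    sq += float(np.sum(resid ** 2))
                    count += len(test)
                results[(C, gamma, eps)] = float(np.sqrt(sq / count))
    best = min(results, key=lambda key: (results[key], key))
    est = SVR(kernel="rbf", C=best[0], gamma=best[1], epsilon=best[2])
    est.fit(Xs, ys)
    return SvrModel(best[0], best[1], best[2], est, x_mean, x_sd, y_mean,
                    y_sd, cv_rmse=results[best],
                    grid_rmse={str(k_): v for k_, v in results.items()})
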