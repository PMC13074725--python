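"""Variable importance in projection (VIP) and the threshold sweep.

VIP scores a wavelength's cumulative contribution to the Y-variance
explained by a PLS model:

    VIP_j = sqrt( p * sum_a s_a (w_ja / ||w_a||)^2 / sum_a s_a )

with p wavelengths, PLS weight vectors w_a and per-component explained
Y-variance s_a = (t_a' t_a)(q_a' q_a).  By construction mean(VIP^2) = 1, so
scores above ~1 mark above-average wavelengths.  The sweep evaluates a
threshold grid (default 0.1..1.2, step 0.1) by refitting the benchmark model
on surviving wavelengths under 10-fold cross-validation and keeps the
threshold minimizing RMSECV (regression) or CVER (classification); ties go
to the larger threshold (fewer variables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemo_models import (_fit_centered_pls, cross_val_error_rate_plsda,
                           cross_val_rmse_plsr, select_lvs_mccv)
from .spectra_core import SpectralDataset

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.1, 1.25, 0.1), 10))


def vip_scores(X: np.ndarray, Y: np.ndarray, n_lv: int) -> np.ndarray:
    """Per-variable VIP scores from an ``n_lv``-component PLS fit.

    ``Y`` may be a single response vector or a one-hot class matrix; the
    explained variance s_a sums over Y columns.
    """
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float).reshape(len(X), -1)
    if np.all(Y.std(axis=0) == 0):
        raise ValueError("degenerate Y: zero variance")
    n_lv = int(min(n_lv, X.shape[1], len(X) - 1))
    model, _, _ = _fit_centered_pls(X, Y, n_lv)
    W = model.x_weights_            # (p, A)
    T = model.x_scores_             # (n, A)
    Q = model.y_loadings_           # (q, A)
    s = np.einsum("na,na->a", T, T) * np.einsum("qa,qa->a", Q, Q)
    w_norm = W / np.linalg.norm(W, axis=0, keepdims=True)
    p = X.shape[1]
    return np.sqrt(p * (w_norm ** 2) @ s / s.sum())


@dataclass
class VipResult:
    """Outcome of a VIP threshold sweep for one task."""

    scores: np.ndarray
    thresholds: np.ndarray
    criterion: np.ndarray          # NaN where a threshold kept no wavelength
    best_threshold: float
    selected: np.ndarray           # wavelength indices at best_threshold
    n_lv: int
    task: str
    meta: dict = field(default_factory=dict)

    def selected_wavelengths(self, ds: SpectralDataset) -> np.ndarray:
        return ds.grid.values[self.selected]


def _one_hot(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels))
    return np.stack([(labels == c).astype(float) for c in classes], axis=1)


def vip_sweep(ds_cal: SpectralDataset, task: str,
              grid=DEFAULT_THRESHOLD_GRID, k: int = 10, seed: int = 0,
              n_lv: int | None = None, mccv_splits: int = 30) -> VipResult:
    """Sweep VIP thresholds for one task on the calibration set.

    The LV count is fixed once per task — chosen by MCCV/PRESS on the
    full-spectrum fit — and held across thresholds so the sweep isolates the
    effect of wavelength selection.
    """
    grid = np.asarray(sorted(grid), float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    X = ds_cal.absorbance
    if task == "classify":
        Y = _one_hot(ds_cal.target("classify"))
    else:
        Y = ds_cal.target(task).reshape(-1, 1)
    if n_lv is None:
        n_lv, _ = select_lvs_mccv(X, Y, n_splits=mccv_splits, seed=seed)
    scores = vip_scores(X, Y, n_lv)

    criterion = np.full(grid.size, np.nan)
    for i, thr in enumerate(grid):
        keep = np.flatnonzero(scores >= thr)
        if keep.size == 0:
            continue
        if task == "classify":
            criterion[i] = cross_val_error_rate_plsda(
                X[:, keep], ds_cal.target("classify"), n_lv, k=k, seed=seed)
        else:
            criterion[i] = cross_val_rmse_plsr(
                X[:, keep], ds_cal.target(task), n_lv, k=k, seed=seed)
    if np.all(np.isnan(criterion)):
        raise ValueError("every threshold retained zero wavelengths")
    best_value = np.nanmin(criterion)
    best_i = int(np.flatnonzero(criterion == best_value)[-1])  # larger thr
    best_threshold = float(grid[best_i])
    return VipResult(
        scores=scores, thresholds=grid, criterion=criterion,
        best_threshold=best_threshold,
        selected=np.flatnonzero(scores >= best_threshold),
        n_lv=int(n_lv), task=task,
        meta={"k": k, "seed": seed, "mccv_splits": mccv_splits})
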