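"""Sample-set partitioning: random test holdout and the SPXY algorithm.

The study protocol splits a dataset 2:1:1 into calibration, validation and
test sets: a uniformly random holdout first isolates the independent test
set, then SPXY (sample-set partitioning based on joint X-Y distances) picks
the calibration samples from the remainder by deterministic max-min
selection on the normalized sum of spectral and response distances

    d(i, j) = d_X(i, j) / max d_X  +  d_Y(i, j) / max d_Y .

With no response (``Y=None``) the selection degenerates to Kennard-Stone on
the spectral distance alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .spectra_core import DatasetSplit, SpectralDataset


@dataclass(frozen=True)
class SplitConfig:
    """Parameters of the 2:1:1 protocol."""

    test_fraction: float = 0.25
    cal_val_ratio: tuple = (2, 1)
    seed: int = 0
    y_mode: str = "regression_targets"   # or "none"

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if min(self.cal_val_ratio) <= 0:
            raise ValueError("cal_val_ratio parts must be positive")


def random_holdout(n: int, n_test: int, seed: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random test holdout without replacement (PCG64 stream).

    Returns ``(remaining, test)`` index arrays, both sorted, disjoint and
    exhaustive over ``0..n-1``; identical for identical seeds.
    """
    if not 0 < n_test < n:
        raise ValueError("n_test must satisfy 0 < n_test < n")
    rng = np.random.default_rng(seed)
    test = np.sort(rng.choice(n, size=n_test, replace=False))
    remaining = np.setdiff1d(np.arange(n), test)
    return remaining, test


def _normalized_distance(M: np.ndarray) -> np.ndarray:
    D = squareform(pdist(M))
    d_max = D.max()
    if d_max == 0:
        raise ValueError("all samples identical; max distance is zero")
    return D / d_max


def spxy_split(X: np.ndarray, Y: np.ndarray | None, n_cal: int,
               standardize_y: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic SPXY max-min selection of ``n_cal`` calibration samples.

    The two mutually farthest samples seed the selection; each step then adds
    the sample whose minimum joint distance to the selected set is largest
    (ties: lowest index).  Returns ``(calibration, validation)`` indices.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n = len(X)
    if n_cal < 2:
        raise ValueError("n_cal must be >= 2")
    if n_cal > n - 1:
        raise ValueError("n_cal must leave at least one validation sample")
    D = _normalized_distance(X)
    if Y is not None:
        Ym = np.asarray(Y, float).reshape(n, -1)
        if standardize_y:
            sd = Ym.std(axis=0, ddof=1)
            Ym = (Ym - Ym.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        D = D + _normalized_distance(Ym)

    # seed pair: maximum joint distance, first pair in row-major order on ties
    iu = np.triu_indices(n, k=1)
    flat_best = np.argmax(D[iu])
    selected = [int(iu[0][flat_best]), int(iu[1][flat_best])]
    remaining = [i for i in range(n) if i not in selected]
    while len(selected) < n_cal:
        d_min = D[np.ix_(remaining, selected)].min(axis=1)
        pick = int(np.argmax(d_min))   # first max -> lowest index tie-break
        selected.append(remaining.pop(pick))
    return np.array(sorted(selected)), np.array(sorted(remaining))


def split_dataset(ds: SpectralDataset, cfg: SplitConfig = SplitConfig()
                  ) -> DatasetSplit:
    """Full 2:1:1 protocol: random test holdout, then SPXY on the remainder.

    With the defaults on a 336-sample dataset this yields sizes
    (168, 84, 84).
    """
    n = ds.n_samples
    n_test = int(round(cfg.test_fraction * n))
    remaining, test = random_holdout(n, n_test, cfg.seed)
    a, b = cfg.cal_val_ratio
    n_cal = int(round(len(remaining) * a / (a + b)))
    Y = None
    if cfg.y_mode == "regression_targets":
        cols = [v for v in (ds.alcohol, ds.wort) if v is not None]
        if not cols:
            raise ValueError("y_mode=regression_targets needs a target")
        Y = np.stack(cols, axis=1)[remaining]
    cal_rel, val_rel = spxy_split(ds.absorbance[remaining], Y, n_cal)
    return DatasetSplit(remaining[cal_rel], remaining[val_rel], test,
                        seed=cfg.seed,
                        meta={"rng": "numpy PCG64", "protocol": "RS+SPXY",
                              "ratio": list(cfg.cal_val_ratio),
                              "test_fraction": cfg.test_fraction})
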