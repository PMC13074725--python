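"""Bayesian optimization of extractor hyperparameters and task weights.

Fitness is 10-fold cross-validated: RMSECV on the min-max-scaled target for
single-task regression, CVER for single-task classification, and for the
multi-task strategy the weighted joint error

    WJE = w_alc * RMSECV_alc / N_alc + w_wort * RMSECV_wort / N_wort
          + w_cls * CVER / N_cls

whose normalization factors N default to each task's best single-task
fitness, converting physical errors to relative performance ratios so no
task dominates by magnitude.  The optimizer is a Gaussian-process surrogate
(Matern 5/2, sklearn) with expected-improvement acquisition over a
unit-cube transform of the space; integer dimensions round post-acquisition
and the weight simplex is one categorical dimension over the 36-point
0.1-resolution grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import KFold, StratifiedKFold

from .deep_features import (NetworkConfig, TrainConfig, build_network,
                            train_mtl, train_stl)
from .spectra_core import SpectralDataset

FAILED_FITNESS = float("inf")


@dataclass(frozen=True)
class TaskWeights:
    """A point on the (w_alc, w_wort, w_cls) simplex.

    The searchable grid restricts each weight to >= 0.1 at 0.1 resolution;
    ``validate=False`` admits degenerate vertices for analysis.
    """

    w_alc: float
    w_wort: float
    w_cls: float
    validate: bool = True

    def __post_init__(self) -> None:
        w = self.as_tuple()
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.validate:
            if min(w) < 0.1 - 1e-9:
                raise ValueError("each task weight must be >= 0.1")
            if any(abs(round(x * 10) - x * 10) > 1e-9 for x in w):
                raise ValueError("weights must lie on the 0.1 grid")
        elif min(w) < 0:
            raise ValueError("weights must be nonnegative")

    def as_tuple(self) -> tuple:
        return (self.w_alc, self.w_wort, self.w_cls)


def wje(rmsecv_alc: float, rmsecv_wort: float, cver: float,
        weights: TaskWeights, norms) -> float:
    """Weighted joint error of the three normalized task fitnesses."""
    n_alc, n_wort, n_cls = norms
    if min(n_alc, n_wort, n_cls) <= 0:
        raise ValueError("normalization factors must be positive")
    w = weights.as_tuple() if isinstance(weights, TaskWeights) else weights
    return (w[0] * rmsecv_alc / n_alc + w[1] * rmsecv_wort / n_wort
            + w[2] * cver / n_cls)


@dataclass
class MTLFitness:
    """Per-task cross-validated errors and their weighted joint error."""

    rmsecv_alc: float
    rmsecv_wort: float
    cver: float
    norms: tuple
    weights: TaskWeights
    wje: float


def enumerate_weight_simplex(step: float = 0.1, min_w: float = 0.1,
                             tasks: int = 3) -> list:
    """All task-weight grid points with components >= min_w summing to 1."""
    inv = Fraction(1) / Fraction(step).limit_denominator(1000)
    if inv.denominator != 1:
        raise ValueError("step must divide 1 exactly")
    total = int(inv)
    floor_units = math.ceil(round(min_w * total, 9))
    if floor_units * tasks > total:
        raise ValueError("infeasible: min_w * tasks exceeds 1")

    def compositions(remaining: int, parts: int):
        if parts == 1:
            if remaining >= floor_units:
                yield (remaining,)
            return
        for first in range(floor_units, remaining - floor_units * (parts - 1)
                           + 1):
            for rest in compositions(remaining - first, parts - 1):
                yield (first,) + rest

    points = [tuple(u / total for u in c)
              for c in compositions(total, tasks)]
    if tasks == 3:
        return [TaskWeights(*p) for p in points]
    return points


# ---------------------------------------------------------------------------
# cross-validated network fitness
# ---------------------------------------------------------------------------

def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 1009 + fold * 9973) & 0x7FFFFFFF


def cv_fitness(config: NetworkConfig, ds_cal: SpectralDataset,
               task: str | None = None, weights: TaskWeights | None = None,
               norms=None, k: int = 10, seed: int = 0,
               train_cfg: TrainConfig | None = None):
    """k-fold cross-validated fitness of one network configuration.

    Single-task mode (``task`` given) returns pooled RMSECV on the scaled
    target or pooled CVER.  Multi-task mode (``weights`` given, ``norms``
    required) trains the shared trunk per fold and returns an
    :class:`MTLFitness`.  A diverged fold yields the +inf sentinel.
    """
    if (task is None) == (weights is None):
        raise ValueError("give exactly one of task= or weights=")
    if ds_cal.n_samples < k:
        raise ValueError("insufficient samples for the requested folds")
    base_cfg = train_cfg or TrainConfig()
    X = ds_cal.absorbance
    mtl = weights is not None
    if mtl:
        if norms is None:
            raise ValueError("multi-task fitness requires norms")
        if not ds_cal.has_targets("alcohol", "wort", "classify"):
            raise ValueError("mtl requires all three targets")
        labels = ds_cal.target("classify")
        folds = StratifiedKFold(k, shuffle=True, random_state=seed
                                ).split(X, labels)
    elif task == "classify":
        labels = ds_cal.target("classify")
        folds = StratifiedKFold(k, shuffle=True, random_state=seed
                                ).split(X, labels)
    else:
        folds = KFold(k, shuffle=True, random_state=seed).split(X)

    heads = ("alcohol", "wort", "classify") if mtl else (task,)
    sq = {"alcohol": 0.0, "wort": 0.0}
    n_reg = 0
    miss, n_cls = 0, 0
    try:
        for fold, (train, test) in enumerate(folds):
            fs = _fold_seed(seed, fold)
            net = build_network(config, X.shape[1], heads, init_seed=fs)
            fold_cfg = TrainConfig(base_cfg.epochs, base_cfg.batch_size,
                                   base_cfg.lr_drop_period, fs)
            if mtl:
                ex = train_mtl(net, X[train], ds_cal.alcohol[train],
                               ds_cal.wort[train], labels[train],
                               weights.as_tuple(), fold_cfg)
            else:
                ex = train_stl(net, X[train], ds_cal.target(task)[train],
                               task, fold_cfg)
            for t in ex.tasks:
                if t == "classify":
                    pred = ex.predict(X[test], "classify")
                    miss += int(np.sum(pred != labels[test]))
                    n_cls += len(test)
                else:
                    pred = ex.predict_scaled(X[test], t)
                    ref = ex.scalers[t].transform(ds_cal.target(t)[test])
                    sq[t] += float(np.sum((pred - ref) ** 2))
            n_reg += len(test)
    except RuntimeError:
        return FAILED_FITNESS

    if not mtl:
        if task == "classify":
            return miss / n_cls
        return float(np.sqrt(sq[task] / n_reg))
    rmse_alc = float(np.sqrt(sq["alcohol"] / n_reg))
    rmse_wort = float(np.sqrt(sq["wort"] / n_reg))
    cver = miss / n_cls if n_cls else 0.0  # zero-weight vertex: head unused
    return MTLFitness(rmse_alc, rmse_wort, cver, tuple(norms), weights,
                      wje(rmse_alc, rmse_wort, cver, weights, norms))


# ---------------------------------------------------------------------------
# search space and GP/EI optimizer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dimension:
    """One search dimension: integer, real, log-real, or categorical."""

    name: str
    kind: str                       # "int" | "real" | "log" | "cat"
    low: float = 0.0
    high: float = 0.0
    choices: tuple = ()

    def __post_init__(self) -> None:
        if self.kind == "cat":
            if not self.choices:
                raise ValueError(f"{self.name}: empty categorical")
        elif self.low >= self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.kind == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log dimension must be positive")

    def from_unit(self, u: float):
        u = min(max(u, 0.0), 1.0)
        if self.kind == "int":
            return int(min(self.high,
                           math.floor(self.low + u * (self.high - self.low
                                                      + 1))))
        if self.kind == "real":
            return self.low + u * (self.high - self.low)
        if self.kind == "log":
            lo, hi = math.log10(self.low), math.log10(self.high)
            return 10.0 ** (lo + u * (hi - lo))
        idx = min(len(self.choices) - 1, int(u * len(self.choices)))
        return self.choices[idx]


@dataclass
class SearchSpace:
    dimensions: list

    def decode(self, unit: np.ndarray) -> dict:
        return {d.name: d.from_unit(float(u))
                for d, u in zip(self.dimensions, unit)}

    def __len__(self) -> int:
        return len(self.dimensions)


def default_search_space(arch: str, include_weights: bool = False,
                         reduced: bool = False) -> SearchSpace:
    """Hyperparameter ranges bracketing the architectures' useful regimes.

    ``reduced=True`` narrows capacity ranges for quick CPU-bound runs.
    """
    dims = []
    has_conv = arch in ("cnn_mha", "cnn_lstm_mha")
    has_lstm = arch in ("lstm_mha", "cnn_lstm_mha")
    if has_conv:
        dims += [Dimension("f_small", "int", 2, 5),
                 Dimension("f_mid", "int", 6, 12),
                 Dimension("f_large", "int", 15, 25),
                 Dimension("num_filters", "int", 8, 16 if reduced else 32)]
    if has_lstm:
        dims += [Dimension("lstm_hidden_units", "int", 16 if reduced else 32,
                           48 if reduced else 160),
                 Dimension("learn_rate_drop_factor", "real", 0.2, 0.9),
                 Dimension("dropout_rate", "real", 0.1, 0.3)]
    dims += [Dimension("feature_dimension", "int", 20,
                       80 if reduced else 200),
             Dimension("initial_learn_rate", "log", 1e-3,
                       0.03 if reduced else 0.1),
             Dimension("l2_regularization", "log", 1e-10, 1e-4)]
    if include_weights:
        dims.append(Dimension("task_weights", "cat",
                              choices=tuple(enumerate_weight_simplex())))
    return SearchSpace(dims)


@dataclass
class BOAResult:
    best_point: dict
    best_fitness: float
    trace: list = field(default_factory=list)  # (point, fitness, best so far)


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float
                          ) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


def optimize(space: SearchSpace, objective, n_iter: int = 50,
             n_init: int = 8, seed: int = 0,
             n_candidates: int = 1024) -> BOAResult:
    """GP-surrogate minimization with expected-improvement acquisition.

    ``objective`` maps a decoded point dict to a scalar (lower is better;
    +inf marks a failed evaluation and is replaced by a large finite
    penalty before surrogate fitting).  The trace records every evaluation
    with the running best.
    """
    n_init = max(1, min(n_init, n_iter))
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    d = len(space)
    if d == 0:
        value = float(objective({}))
        return BOAResult({}, value, [({}, value, value)])
    rng = np.random.default_rng(seed)
    sobol = qmc.Sobol(d=max(d, 1), scramble=True, seed=seed)
    unit_points = []
    values = []
    trace = []
    best_value, best_point = float("inf"), None

    def evaluate(u: np.ndarray) -> None:
        nonlocal best_value, best_point
        point = space.decode(u)
        value = float(objective(point))
        unit_points.append(u)
        values.append(value)
        if value < best_value:
            best_value, best_point = value, point
        trace.append((point, value, best_value))

    n_draw = 1 << max(0, (n_init - 1).bit_length())  # power of 2 for Sobol
    for u in sobol.random(n_draw)[:n_init]:
        evaluate(np.asarray(u[:d]))
        if len(trace) >= n_iter:
            break
    if not np.isfinite(np.asarray(values)).any():
        raise RuntimeError("objective non-finite at all initial points")

    kernel = Matern(nu=2.5, length_scale=np.full(max(d, 1), 0.3),
                    length_scale_bounds=(1e-2, 10.0))
    while len(trace) < n_iter:
        y = np.asarray(values)
        finite = np.isfinite(y)
        if not finite.any():
            raise RuntimeError("objective non-finite at all initial points")
        penalty = 10.0 * np.abs(y[finite]).max() + 1.0
        y = np.where(finite, y, penalty)
        gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6,
                                      normalize_y=True,
                                      random_state=seed & 0x7FFFFFFF)
        gp.fit(np.asarray(unit_points), y)
        cand = rng.random((n_candidates, d))
        mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, y.min())
        evaluate(cand[int(np.argmax(ei))])
    return BOAResult(best_point, best_value, trace)
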