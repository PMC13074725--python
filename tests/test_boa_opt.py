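import numpy as np
import pytest

from nirmtl.boa_opt import (Dimension, MTLFitness, SearchSpace, TaskWeights,
                            cv_fitness, default_search_space,
                            enumerate_weight_simplex, optimize, wje)
from nirmtl.deep_features import NetworkConfig, TrainConfig
from nirmtl.spectra_core import SpectralDataset, WavelengthGrid


class TestWje:
    def test_degenerate_vertex(self):
        w = TaskWeights(1.0, 0.0, 0.0, validate=False)
        assert wje(0.5, 9.0, 0.4, w, (1, 1, 1)) == pytest.approx(0.5)

    def test_errors_equal_norms_give_one(self):
        w = TaskWeights(0.2, 0.3, 0.5)
        assert wje(0.03, 0.7, 0.11, w, (0.03, 0.7, 0.11)) == pytest.approx(1)

    def test_hand_computed_example(self):
        w = TaskWeights(0.3, 0.5, 0.2)
        assert wje(0.04, 0.06, 0.0, w,
                   (0.02, 0.04, 0.05)) == pytest.approx(1.35)

    def test_nonpositive_norm_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            wje(1, 1, 1, TaskWeights(0.3, 0.5, 0.2), (0.0, 1, 1))

    def test_norm_scaling_linearity(self):
        w = TaskWeights(0.3, 0.5, 0.2)
        base = wje(0.1, 0.2, 0.05, w, (0.5, 0.3, 0.2))
        scaled = wje(0.1, 0.2, 0.05, w, (1.5, 0.9, 0.6))
        assert scaled == pytest.approx(base / 3.0)


class TestTaskWeights:
    def test_grid_membership_enforced(self):
        TaskWeights(0.3, 0.5, 0.2)
        with pytest.raises(ValueError, match="sum to 1"):
            TaskWeights(0.5, 0.6, 0.2)
        with pytest.raises(ValueError, match=">= 0.1"):
            TaskWeights(0.05, 0.9, 0.05)

    def test_simplex_enumeration_count(self):
        points = enumerate_weight_simplex()
        assert len(points) == 36
        assert TaskWeights(0.3, 0.5, 0.2) in points

    def test_infeasible_floor(self):
        with pytest.raises(ValueError, match="infeasible"):
            enumerate_weight_simplex(min_w=0.4)


class TestOptimize:
    def test_single_point_space(self):
        space = SearchSpace([Dimension("c", "cat", choices=("only",))])
        calls = []
        result = optimize(space, lambda p: calls.append(p) or 1.0,
                          n_iter=1, seed=0)
        assert result.best_point == {"c": "only"} and len(calls) == 1

    def test_one_dimensional_quadratic(self):
        space = SearchSpace([Dimension("x", "real", 0.0, 1.0)])
        result = optimize(space, lambda p: (p["x"] - 0.3) ** 2, n_iter=50,
                          seed=0)
        assert abs(result.best_point["x"] - 0.3) < 0.05

    def test_trace_best_monotone(self):
        rng = np.random.default_rng(0)
        space = SearchSpace([Dimension("x", "real", -1, 1),
                             Dimension("k", "int", 1, 5)])
        result = optimize(space,
                          lambda p: p["x"] ** 2 + 0.1 * p["k"]
                          + rng.normal(0, 0.01),
                          n_iter=20, seed=1)
        best = [b for _, _, b in result.trace]
        assert all(a >= b for a, b in zip(best, best[1:]))

    def test_beats_random_search_on_convex_function(self):
        def objective(p):
            return (p["x"] - 0.2) ** 2 + (p["y"] + 0.4) ** 2

        space = SearchSpace([Dimension("x", "real", -1, 1),
                             Dimension("y", "real", -1, 1)])
        budget = 20
        gp_best, rnd_best = [], []
        for seed in range(10):
            gp_best.append(optimize(space, objective, n_iter=budget,
                                    seed=seed).best_fitness)
            rng = np.random.default_rng(seed)
            rnd_best.append(min(objective(space.decode(u))
                                for u in rng.random((budget, 2))))
        assert np.median(gp_best) < np.median(rnd_best)

    def test_all_initial_failures_rejected(self):
        space = SearchSpace([Dimension("x", "real", 0, 1)])
        with pytest.raises(RuntimeError, match="non-finite"):
            optimize(space, lambda p: float("inf"), n_iter=3, n_init=3,
                     seed=0)

    def test_failed_evaluations_penalized_not_fatal(self):
        space = SearchSpace([Dimension("x", "real", 0, 1)])

        def objective(p):
            return float("inf") if p["x"] > 0.8 else p["x"]

        result = optimize(space, objective, n_iter=15, seed=2)
        assert np.isfinite(result.best_fitness)

    def test_log_dimension_positive(self):
        with pytest.raises(ValueError, match="positive"):
            Dimension("lr", "log", 0.0, 1.0)


def _tiny_dataset(n=24, p=12, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 0.3, (n, p))
    y = X[:, 1] - 0.5 * X[:, 7]
    labels = np.where(y > 0, "craft", "industrial").astype(object)
    return SpectralDataset(WavelengthGrid(np.linspace(900, 1700, p)), X,
                           np.array([f"s{i}" for i in range(n)],
                                    dtype=object),
                           alcohol=5 + y, wort=12 + 2 * y,
                           class_label=labels)


TINY_NET = dict(f_small=2, f_mid=3, f_large=5, num_filters=2,
                lstm_hidden_units=4, feature_dimension=6)
TINY_TRAIN = TrainConfig(epochs=4, batch_size=8, seed=0)


class TestCvFitness:
    def test_deterministic(self):
        ds = _tiny_dataset()
        cfg = NetworkConfig(arch="cnn_mha", **TINY_NET)
        a = cv_fitness(cfg, ds, task="alcohol", k=3, seed=5,
                       train_cfg=TINY_TRAIN)
        b = cv_fitness(cfg, ds, task="alcohol", k=3, seed=5,
                       train_cfg=TINY_TRAIN)
        assert a == b

    def test_classification_error_in_range(self):
        ds = _tiny_dataset(seed=1)
        cfg = NetworkConfig(arch="cnn_mha", **TINY_NET)
        cver = cv_fitness(cfg, ds, task="classify", k=3, seed=0,
                          train_cfg=TINY_TRAIN)
        assert 0.0 <= cver <= 1.0

    def test_mtl_returns_wje_consistent_fitness(self):
        ds = _tiny_dataset(seed=2)
        cfg = NetworkConfig(arch="cnn_mha", **TINY_NET)
        norms = (0.1, 0.1, 0.2)
        fit = cv_fitness(cfg, ds, weights=TaskWeights(0.3, 0.5, 0.2),
                         norms=norms, k=3, seed=0, train_cfg=TINY_TRAIN)
        assert isinstance(fit, MTLFitness)
        assert fit.wje == pytest.approx(
            wje(fit.rmsecv_alc, fit.rmsecv_wort, fit.cver, fit.weights,
                norms))

    def test_mtl_vertex_wje_reduces_to_single_task(self):
        # exact STL/MTL loss agreement at a simplex vertex is covered at the
        # training level; here the vertex WJE must equal the alcohol term
        ds = _tiny_dataset(seed=3)
        cfg = NetworkConfig(arch="cnn_mha", **TINY_NET)
        mtl = cv_fitness(cfg, ds,
                         weights=TaskWeights(1.0, 0.0, 0.0, validate=False),
                         norms=(1.0, 1.0, 1.0), k=3, seed=4,
                         train_cfg=TINY_TRAIN)
        assert mtl.wje == pytest.approx(mtl.rmsecv_alc)

    def test_requires_exactly_one_mode(self):
        ds = _tiny_dataset()
        cfg = NetworkConfig(arch="cnn_mha", **TINY_NET)
        with pytest.raises(ValueError):
            cv_fitness(cfg, ds)
        with pytest.raises(ValueError, match="norms"):
            cv_fitness(cfg, ds, weights=TaskWeights(0.3, 0.5, 0.2), k=3)


class TestSearchSpace:
    @pytest.mark.parametrize("arch,names", [
        ("cnn_mha", {"f_small", "f_mid", "f_large", "num_filters"}),
        ("lstm_mha", {"lstm_hidden_units", "dropout_rate"}),
        ("cnn_lstm_mha", {"f_small", "lstm_hidden_units"}),
    ])
    def test_architecture_dimensions(self, arch, names):
        space = default_search_space(arch)
        dims = {d.name for d in space.dimensions}
        assert names <= dims
        assert {"feature_dimension", "initial_learn_rate",
                "l2_regularization"} <= dims

    def test_weight_dimension_optional(self):
        space = default_search_space("cnn_mha", include_weights=True)
        cats = [d for d in space.dimensions if d.kind == "cat"]
        assert len(cats) == 1 and len(cats[0].choices) == 36

    def test_decode_respects_bounds(self):
        space = default_search_space("cnn_lstm_mha", include_weights=True)
        rng = np.random.default_rng(0)
        for u in rng.random((50, len(space))):
            point = space.decode(u)
            assert 2 <= point["f_small"] <= 5
            assert 1e-10 <= point["l2_regularization"] <= 1e-4
            assert isinstance(point["task_weights"], TaskWeights)
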