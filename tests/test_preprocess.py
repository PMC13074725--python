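import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirmtl.preprocess import (PreprocessMethod, PreprocessScoreTable,
                               apply_chain, apply_ftd, apply_msc, apply_sg,
                               apply_snv, apply_wd, benchmark_method, mcps)
from nirmtl.spectra_core import SpectralDataset, WavelengthGrid

from conftest import random_dataset


class TestSnv:
    def test_forced_example(self):
        np.testing.assert_allclose(apply_snv([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2, 50)
        once = apply_snv(x)
        np.testing.assert_allclose(apply_snv(once), once, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            apply_snv([5.0, 5.0, 5.0])


class TestMsc:
    def test_reference_unchanged(self, small_ds):
        ref = small_ds.absorbance.mean(axis=0)
        ds = SpectralDataset(small_ds.grid,
                             np.vstack([ref, small_ds.absorbance]),
                             np.array([f"r{i}" for i in range(
                                 small_ds.n_samples + 1)], dtype=object))
        out = apply_msc(ds, reference=ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)

    def test_affine_inversion(self, small_ds):
        ref = small_ds.absorbance.mean(axis=0)
        scaled = SpectralDataset(small_ds.grid, 2.0 * ref + 3.0
                                 + np.zeros((1, len(ref))),
                                 np.array(["x"], dtype=object))
        out = apply_msc(scaled, reference=ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-9)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        ds = random_dataset(n=3, p=25, seed=7)
        ref = ds.absorbance.mean(axis=0)
        out = apply_msc(ds, reference=ref)
        A = np.column_stack([np.ones_like(ref), ref])
        for i in range(3):
            a, b = np.linalg.lstsq(A, ds.absorbance[i], rcond=None)[0]
            np.testing.assert_allclose(out.absorbance[i],
                                       (ds.absorbance[i] - a) / b,
                                       atol=1e-9)


class TestSg:
    def test_polynomial_reproduced(self):
        x = np.linspace(0, 1, 60)
        poly = 2.0 + 0.5 * x - 1.2 * x ** 2
        np.testing.assert_allclose(apply_sg(poly, 11, 2), poly, atol=1e-9)

    def test_smooths_noise(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 2 * np.pi, 228)
        clean = np.sin(t)
        noisy = clean + rng.normal(0, 0.1, t.size)
        smoothed = apply_sg(noisy, 11, 2)
        assert np.var(smoothed - clean) < np.var(noisy - clean)

    @pytest.mark.parametrize("window,poly", [(4, 2), (5, 5), (301, 2)])
    def test_invalid_parameters(self, window, poly):
        with pytest.raises(ValueError):
            apply_sg(np.zeros(228), window, poly)


class TestWd:
    def test_zero_vector(self):
        np.testing.assert_allclose(apply_wd(np.zeros(64)), np.zeros(64))

    def test_smooth_signal_passes(self):
        x = np.linspace(-1, 1, 128)
        poly = 1.0 + x + 0.5 * x ** 2
        np.testing.assert_allclose(apply_wd(poly), poly, atol=1e-6)

    def test_noise_variance_shrinks(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1, 256)
        assert np.var(apply_wd(noise)) < np.var(noise)

    def test_infeasible_level(self):
        with pytest.raises(ValueError, match="infeasible"):
            apply_wd(np.zeros(16), level=6)


class TestFtd:
    def test_identity_at_full_cutoff(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 100)
        np.testing.assert_allclose(apply_ftd(x, 1.0), x, atol=1e-9)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(apply_ftd(np.full(50, 2.5), 0.2),
                                   np.full(50, 2.5), atol=1e-10)

    def test_high_frequency_removed(self):
        n = 128
        t = np.arange(n)
        # frequency bin 40 of 64 is above 0.3 * Nyquist
        x = np.cos(2 * np.pi * 40 * t / n)
        assert np.max(np.abs(apply_ftd(x, 0.3))) < 1e-6

    @pytest.mark.parametrize("cutoff", [0.0, -0.5, 1.5])
    def test_invalid_cutoff(self, cutoff):
        with pytest.raises(ValueError):
            apply_ftd(np.zeros(10), cutoff)


class TestChains:
    def test_chain_applies_in_order(self):
        ds = random_dataset(n=6, p=64, seed=2)
        method = PreprocessMethod.from_spec("WD+FTD")
        out = apply_chain(ds, method)
        manual = np.stack([apply_ftd(apply_wd(row))
                           for row in ds.absorbance])
        np.testing.assert_allclose(out.absorbance, manual, atol=1e-12)

    def test_snv_chain_is_rowwise_snv(self, small_ds):
        out = apply_chain(small_ds, PreprocessMethod.from_spec("SNV"))
        manual = np.stack([apply_snv(r) for r in small_ds.absorbance])
        np.testing.assert_allclose(out.absorbance, manual)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            PreprocessMethod("empty", ())

    def test_repeated_operator_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            PreprocessMethod.from_spec("SNV+SNV")

    def test_targets_untouched(self, small_ds):
        out = apply_chain(small_ds, PreprocessMethod.from_spec("SG"))
        assert np.array_equal(out.alcohol, small_ds.alcohol)


def _linear_mixture_dataset(n=40, p=30, seed=0):
    """Noise-free spectra whose alcohol target is exactly linear in them."""
    rng = np.random.default_rng(seed)
    grid = WavelengthGrid(np.linspace(900, 1700, p))
    basis = rng.normal(0, 1, (3, p))
    conc = rng.uniform(1, 5, (n, 3))
    X = conc @ basis
    return SpectralDataset(grid, X,
                           np.array([f"s{i}" for i in range(n)],
                                    dtype=object),
                           alcohol=conc[:, 0])


class TestBenchmark:
    def test_noise_free_linear_recovery(self):
        ds = _linear_mixture_dataset()
        method = PreprocessMethod("identity", (("FTD",
                                               {"cutoff_fraction": 1.0}),))
        rmsecv = benchmark_method(ds, method, "alcohol", seed=0)
        assert rmsecv < 1e-6

    def test_separable_classes_zero_error(self):
        rng = np.random.default_rng(2)
        grid = WavelengthGrid(np.linspace(900, 1700, 20))
        X = rng.normal(0, 0.05, (40, 20))
        X[20:, :5] += 4.0      # industrial block shifted far away
        labels = np.array(["craft"] * 20 + ["industrial"] * 20,
                          dtype=object)
        ds = SpectralDataset(grid, X,
                             np.array([f"s{i}" for i in range(40)],
                                      dtype=object),
                             class_label=labels)
        method = PreprocessMethod("identity",
                                  (("FTD", {"cutoff_fraction": 1.0}),))
        assert benchmark_method(ds, method, "classify", seed=0) == 0.0

    def test_too_few_samples(self):
        ds = _linear_mixture_dataset(n=5)
        method = PreprocessMethod.from_spec("SNV")
        with pytest.raises(ValueError, match="insufficient samples"):
            benchmark_method(ds, method, "alcohol")

    def test_deterministic_given_seed(self):
        ds = random_dataset(n=30, p=15, seed=9)
        method = PreprocessMethod.from_spec("SG")
        a = benchmark_method(ds, method, "wort", seed=42)
        b = benchmark_method(ds, method, "wort", seed=42)
        assert a == b


class TestMcps:
    def test_single_method_scores_one(self):
        table = PreprocessScoreTable(["m"], [[0.4, 1.2, 0.02]])
        np.testing.assert_allclose(mcps(table), [1.0])

    def test_hand_computed_example(self):
        table = PreprocessScoreTable(
            ["a", "b"], [[0.4, 1.2, 0.02], [0.5, 1.0, 0.01]])
        np.testing.assert_allclose(mcps(table), [1.4000, 1.0833],
                                   atol=5e-5)

    def test_uniform_best_method_is_minimum_at_one(self):
        table = PreprocessScoreTable(
            ["best", "worse"], [[0.1, 0.2, 0.05], [0.2, 0.3, 0.06]])
        scores = mcps(table)
        assert scores[0] == pytest.approx(1.0)
        assert scores.argmin() == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.floats(0.01, 10.0), min_size=3,
                             max_size=3), min_size=1, max_size=6))
    def test_scores_never_below_one(self, errors):
        table = PreprocessScoreTable([f"m{i}" for i in range(len(errors))],
                                     errors)
        assert np.all(mcps(table) >= 1.0 - 1e-12)

    def test_nonpositive_error_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            mcps(PreprocessScoreTable(["m"], [[0.0, 1.0, 1.0]]))
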