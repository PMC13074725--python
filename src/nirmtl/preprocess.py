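"""Spectral preprocessing operators, chains, and multi-task method selection.

Implements the five classical NIR preprocessing operators — Savitzky-Golay
smoothing (SG), multiplicative scatter correction (MSC), standard normal
variate (SNV), wavelet denoising (WD) and Fourier-transform denoising (FTD) —
their ordered combinations, a 10-fold cross-validated benchmark (PLSR for the
regression tasks, PLS-DA for authentication), and the multi-task
comprehensive performance score (MCPS) used to pick one preprocessing method
for joint multi-task modelling:

    MCPS_i = sum_j  w_j * E[i, j] / min_i' E[i', j]

where ``E[i, j]`` is the cross-validated error of method ``i`` on task ``j``
and the minimum runs over all candidate methods.  MCPS is >= 1 with equality
iff a method is simultaneously best on every task; the selected method is the
argmin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import savgol_filter

from .spectra_core import SpectralDataset
from .chemo_models import cross_val_rmse_plsr, cross_val_error_rate_plsda

OPERATORS = ("SG", "MSC", "SNV", "WD", "FTD")

TASKS = ("alcohol", "wort", "classify")

#: benchmark latent-variable cap used during preprocessing screening
BENCHMARK_LVS = 10


def apply_snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and unit scaling.

    Uses the sample standard deviation (divisor n-1).
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ValueError("spectrum too short for SNV")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance spectrum")
    return (x - x.mean()) / sd


def apply_msc(ds: SpectralDataset, reference: np.ndarray | None = None
              ) -> SpectralDataset:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference, x ~ a + b*ref, and
    replaced by (x - a) / b.  The reference defaults to the mean spectrum of
    ``ds``; pass the calibration-set mean explicitly to correct validation or
    test data without leakage.
    """
    X = ds.absorbance
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.std() == 0:
        raise ValueError("reference spectrum has zero variance")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(b == 0):
        raise ValueError("degenerate scatter fit")
    a = X.mean(axis=1) - b * ref.mean()
    corrected = (X - a[:, None]) / b[:, None]
    out = SpectralDataset(ds.grid, corrected, ds.sample_id, ds.alcohol,
                          ds.wort, ds.class_label)
    return out


def apply_sg(spectrum: np.ndarray, window: int = 11, polyorder: int = 2
             ) -> np.ndarray:
    """Savitzky-Golay smoothing; edges refit on the truncated window."""
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("SG window must be odd")
    if polyorder >= window:
        raise ValueError("SG polyorder must be smaller than window")
    if window > x.size:
        raise ValueError("SG window exceeds spectrum length")
    return savgol_filter(x, window, polyorder, mode="interp")


def apply_wd(spectrum: np.ndarray, wavelet: str = "db4", level: int = 3,
             rule: str = "soft") -> np.ndarray:
    """Wavelet denoising with the universal threshold.

    Decomposes to ``level`` scales, shrinks detail coefficients with the
    universal threshold sigma*sqrt(2 ln N) (sigma from the median absolute
    deviation of the finest detail scale), and reconstructs.
    """
    x = np.asarray(spectrum, dtype=float)
    if level < 1:
        raise ValueError("decomposition level must be >= 1")
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        raise ValueError(f"level {level} infeasible for length {x.size}")
    coeffs = pywt.wavedec(x, wavelet, level=level)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(x.size))
    denoised = [coeffs[0]]
    if thresh == 0:          # noiseless signal: nothing to shrink
        denoised += coeffs[1:]
    else:
        denoised += [pywt.threshold(c, thresh, mode=rule)
                     for c in coeffs[1:]]
    return pywt.waverec(denoised, wavelet)[: x.size]


def apply_ftd(spectrum: np.ndarray, cutoff_fraction: float = 0.2
              ) -> np.ndarray:
    """Fourier low-pass denoising: zero components above a Nyquist fraction."""
    if not 0 < cutoff_fraction <= 1:
        raise ValueError("cutoff_fraction must be in (0, 1]")
    x = np.asarray(spectrum, dtype=float)
    spec = np.fft.rfft(x)
    n_keep = int(np.floor(cutoff_fraction * (spec.size - 1)))
    spec[n_keep + 1:] = 0.0
    return np.fft.irfft(spec, n=x.size)


@dataclass(frozen=True)
class PreprocessMethod:
    """An ordered chain of preprocessing operators with their parameters."""

    name: str
    chain: tuple  # of (operator, params-dict) pairs

    def __post_init__(self) -> None:
        if not self.chain:
            raise ValueError("preprocessing chain must be nonempty")
        ops = [op for op, _ in self.chain]
        for op in ops:
            if op not in OPERATORS:
                raise ValueError(f"unknown operator {op!r}")
        if len(set(ops)) != len(ops):
            raise ValueError("operator repeated in chain")

    @classmethod
    def from_spec(cls, spec: str, **overrides) -> "PreprocessMethod":
        """Build from a '+'-joined spec such as ``"WD+FTD"``.

        Keyword overrides are routed by operator name, e.g.
        ``ftd={"cutoff_fraction": 0.3}``.
        """
        ops = [s.strip().upper() for s in spec.split("+")]
        chain = tuple((op, dict(overrides.get(op.lower(), {}))) for op in ops)
        return cls(spec, chain)


#: default candidate set: the five singles plus the combinations screened
DEFAULT_CANDIDATES = ("SG", "MSC", "SNV", "WD", "FTD",
                      "WD+FTD", "SG+SNV", "SG+MSC")


def apply_chain(ds: SpectralDataset, method: PreprocessMethod,
                msc_reference: np.ndarray | None = None) -> SpectralDataset:
    """Apply each operator of ``method`` in order; targets are untouched."""
    out = ds
    for op, params in method.chain:
        if op == "MSC":
            out = apply_msc(out, reference=msc_reference, **params)
            continue
        row_fn = {"SG": apply_sg, "SNV": apply_snv,
                  "WD": apply_wd, "FTD": apply_ftd}[op]
        rows = np.stack([row_fn(r, **params) for r in out.absorbance])
        out = SpectralDataset(out.grid, rows, out.sample_id, out.alcohol,
                              out.wort, out.class_label)
    return out


def benchmark_method(ds_cal: SpectralDataset, method: PreprocessMethod,
                     task: str, n_lv: int = BENCHMARK_LVS, k: int = 10,
                     seed: int = 0) -> float:
    """Cross-validated benchmark error of one preprocessing method.

    Applies the chain to the calibration set and evaluates a fixed-LV PLSR
    (RMSECV, regression tasks) or PLS-DA (CVER, classification) under k-fold
    cross-validation.  Folds are stratified by class for classification and
    seeded-random otherwise.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if ds_cal.n_samples < k:
        raise ValueError(f"insufficient samples for {k} folds")
    treated = apply_chain(ds_cal, method)
    X = treated.absorbance
    if task == "classify":
        return cross_val_error_rate_plsda(X, treated.target("classify"),
                                          n_lv=n_lv, k=k, seed=seed)
    return cross_val_rmse_plsr(X, treated.target(task), n_lv=n_lv, k=k,
                               seed=seed)


@dataclass
class PreprocessScoreTable:
    """Per-method, per-task benchmark errors plus task weights."""

    methods: list
    errors: np.ndarray           # shape (n_methods, 3), columns follow TASKS
    weights: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0))

    def __post_init__(self) -> None:
        self.errors = np.atleast_2d(np.asarray(self.errors, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.methods) != self.errors.shape[0]:
            raise ValueError("methods and error rows disagree")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")


def mcps(table: PreprocessScoreTable) -> np.ndarray:
    """Multi-task comprehensive performance scores, one per method."""
    E = table.errors
    if E.shape[0] == 0:
        raise ValueError("no methods to score")
    if np.any(E <= 0):
        raise ValueError("all benchmark errors must be strictly positive")
    ratios = E / E.min(axis=0, keepdims=True)
    return ratios @ table.weights


def select_preprocessing(ds_cal: SpectralDataset,
                         candidates=DEFAULT_CANDIDATES,
                         weights=None, seed: int = 0,
                         k: int = 10) -> tuple:
    """Benchmark candidate chains on all three tasks and pick the MCPS winner.

    Returns ``(best_method, scores, table)``; ``best_method`` is the
    :class:`PreprocessMethod` with the lowest MCPS.
    """
    methods = [PreprocessMethod.from_spec(c) for c in candidates]
    errors = np.empty((len(methods), 3))
    for i, m in enumerate(methods):
        for j, task in enumerate(TASKS):
            errors[i, j] = benchmark_method(ds_cal, m, task, k=k, seed=seed)
            # CVER can be exactly 0 on cleanly separable classes; floor it so
            # the MCPS ratio stays defined without changing the ranking
            errors[i, j] = max(errors[i, j], 1e-12)
    table = PreprocessScoreTable(methods, errors,
                                 np.full(3, 1.0 / 3.0) if weights is None
                                 else np.asarray(weights, float))
    scores = mcps(table)
    return methods[int(np.argmin(scores))], scores, table
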