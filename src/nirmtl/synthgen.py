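"""Synthetic beer NIR spectrum generator.

Emulates transmission NIR spectra of beer on the 228-point 900-1700 nm grid
under a Beer-Lambert measurement model: absorbance is linear in constituent
concentrations, with Gaussian absorption bands placed inside the C-H / O-H
overtone regions (1120-1220, 1360-1440, 1463-1530 and 1620-1700 nm) that
carry the ethanol, sugar and protein signal in this range, on top of the
dominant broad water band near 1450 nm.  Instrumental artefacts are modelled
as a random quadratic baseline, a multiplicative scatter factor and
heteroscedasticity-free additive Gaussian noise:

    A(l) = s * [ alc * eth(l) + wort * (sug(l) + c_class * prot(l))
                 + water(l) ] + baseline(l) + noise .

The default study design mirrors a three-class beer authentication set-up:
138 craft and 78 industrial samples with correlated (alcohol, wort) draws,
plus a full-factorial non-fermented block of 4 alcohol x 5 wort levels x 6
replicates = 120 samples (20 unique ratios), 336 samples in total.  Craft
beer carries the full protein/secondary-metabolite band, industrial beer a
reduced one, and non-fermented imitations none — which is what makes the
classes separable and the imitation detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_core import CLASS_LABELS, SpectralDataset, WavelengthGrid

ALCOHOL_RANGE = (3.0, 12.0)     # % vol
WORT_RANGE = (8.0, 24.0)        # degrees Plato

NON_FERMENTED_ALCOHOL = (3.0, 4.0, 5.0, 7.0)
NON_FERMENTED_WORT = (8.0, 9.0, 10.0, 11.0, 12.0)
NON_FERMENTED_REPLICATES = 6


@dataclass(frozen=True)
class ComponentBand:
    """One Gaussian absorption band: nm center/sigma, strength per unit."""

    center: float
    width: float
    strength: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")


def _bands(*triples) -> tuple:
    return tuple(ComponentBand(*t) for t in triples)


@dataclass
class GeneratorConfig:
    """Band library, artefact levels and sample-design parameters."""

    grid: WavelengthGrid = field(default_factory=WavelengthGrid.uniform)
    # per % vol ethanol: second overtone CH3/CH2, CH combination, first
    # overtone CH regions
    ethanol_bands: tuple = _bands((1170.0, 20.0, 0.010),
                                  (1400.0, 25.0, 0.014),
                                  (1660.0, 28.0, 0.008))
    # per degree Plato dissolved solids (mostly maltose)
    sugar_bands: tuple = _bands((1175.0, 30.0, 0.0045),
                                (1410.0, 32.0, 0.0060),
                                (1680.0, 30.0, 0.0035))
    # protein / secondary-metabolite N-H combination band, per degree Plato
    protein_bands: tuple = _bands((1500.0, 25.0, 0.0080))
    # flavoring / citric-acid additive band carried only by the
    # non-fermented imitation (fixed formulation proportion)
    flavoring_bands: tuple = _bands((1245.0, 18.0, 0.040))
    water_bands: tuple = _bands((1450.0, 60.0, 1.20),
                                (970.0, 35.0, 0.12))
    #: class-dependent multiplier on the protein band; the non-fermented
    #: imitation lacks fermentation metabolites entirely
    protein_coeff: dict = field(default_factory=lambda: {
        "craft": 1.0, "industrial": 0.3, "non_fermented": 0.0})
    noise_sd: float = 0.002                      # absorbance units
    baseline_coeff: tuple = (0.02, 0.01, 0.005)  # quadratic coeff half-ranges
    scatter_range: tuple = (0.95, 1.05)
    #: correlated commercial (alcohol, wort): mean, sd per class and the
    #: alcohol-wort correlation reflecting fermentation stoichiometry
    commercial_dist: dict = field(default_factory=lambda: {
        "craft": {"mean": (5.2, 14.0), "sd": (1.9, 4.0)},
        "industrial": {"mean": (4.0, 11.0), "sd": (0.8, 1.6)}})
    rho: float = 0.8
    n_craft: int = 138
    n_industrial: int = 78
    seed: int = 0


def component_spectrum(bands, grid: WavelengthGrid) -> np.ndarray:
    """Sum of Gaussian band profiles evaluated on the grid."""
    lam = grid.values
    out = np.zeros_like(lam)
    for b in bands:
        out += b.strength * np.exp(-((lam - b.center) ** 2)
                                   / (2.0 * b.width ** 2))
    return out


def generate_sample(cfg: GeneratorConfig, class_label: str, alcohol: float,
                    wort: float, rng: np.random.Generator) -> np.ndarray:
    """One absorbance spectrum for the given composition and class."""
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class {class_label!r}")
    if not (ALCOHOL_RANGE[0] <= alcohol <= ALCOHOL_RANGE[1]) and alcohol != 0:
        raise ValueError("alcohol outside the study range")
    if not (WORT_RANGE[0] <= wort <= WORT_RANGE[1]) and wort != 0:
        raise ValueError("wort outside the study range")
    grid = cfg.grid
    chem = (alcohol * component_spectrum(cfg.ethanol_bands, grid)
            + wort * (component_spectrum(cfg.sugar_bands, grid)
                      + cfg.protein_coeff[class_label]
                      * component_spectrum(cfg.protein_bands, grid))
            + component_spectrum(cfg.water_bands, grid))
    if class_label == "non_fermented":
        chem = chem + component_spectrum(cfg.flavoring_bands, grid)
    scatter = rng.uniform(*cfg.scatter_range)
    u = (grid.values - grid.values.mean()) / (np.ptp(grid.values) / 2.0)
    c0, c1, c2 = (rng.uniform(-h, h) for h in cfg.baseline_coeff)
    baseline = c0 + c1 * u + c2 * u ** 2
    noise = rng.normal(0.0, cfg.noise_sd, size=len(grid)) if cfg.noise_sd \
        else np.zeros(len(grid))
    return scatter * chem + baseline + noise


def _truncated_correlated_pair(cfg: GeneratorConfig, class_label: str,
                               rng: np.random.Generator
                               ) -> tuple[float, float]:
    dist = cfg.commercial_dist[class_label]
    mean = np.asarray(dist["mean"])
    sd = np.asarray(dist["sd"])
    cov = np.array([[sd[0] ** 2, cfg.rho * sd[0] * sd[1]],
                    [cfg.rho * sd[0] * sd[1], sd[1] ** 2]])
    lo = np.array([ALCOHOL_RANGE[0], WORT_RANGE[0]])
    hi = np.array([ALCOHOL_RANGE[1], WORT_RANGE[1]])
    while True:  # rejection sampling onto the admissible rectangle
        draw = rng.multivariate_normal(mean, cov)
        if np.all(draw >= lo) and np.all(draw <= hi):
            return float(draw[0]), float(draw[1])


def generate_study(cfg: GeneratorConfig | None = None) -> SpectralDataset:
    """The full default design: 138 craft + 78 industrial + 120 non-fermented.

    Deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    rows, ids, alc, wort, labels = [], [], [], [], []

    def add(label: str, a: float, w: float) -> None:
        rows.append(generate_sample(cfg, label, a, w, rng))
        ids.append(f"{label}_{len(ids):03d}")
        alc.append(a)
        wort.append(w)
        labels.append(label)

    for label, count in (("craft", cfg.n_craft),
                         ("industrial", cfg.n_industrial)):
        for _ in range(count):
            add(label, *_truncated_correlated_pair(cfg, label, rng))
    for a in NON_FERMENTED_ALCOHOL:
        for w in NON_FERMENTED_WORT:
            for _ in range(NON_FERMENTED_REPLICATES):
                add("non_fermented", a, w)

    return SpectralDataset(cfg.grid, np.stack(rows),
                           np.asarray(ids, dtype=object),
                           np.asarray(alc), np.asarray(wort),
                           np.asarray(labels, dtype=object))
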