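import numpy as np
import pytest

from nirmtl.spectra_core import SpectralDataset, WavelengthGrid
from nirmtl.synthgen import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """The full default 336-sample synthetic study design."""
    return generate_study(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def mini_study():
    """A reduced commercial design for cheap model-fitting tests."""
    cfg = GeneratorConfig(seed=5, n_craft=30, n_industrial=18)
    return generate_study(cfg)


def random_dataset(n=12, p=20, seed=0, with_classes=True):
    """Small random-but-valid dataset for plumbing tests."""
    rng = np.random.default_rng(seed)
    grid = WavelengthGrid(np.linspace(900, 1700, p))
    classes = None
    if with_classes:
        classes = rng.choice(["craft", "industrial", "non_fermented"],
                             size=n)
    return SpectralDataset(
        grid=grid,
        absorbance=rng.normal(0.5, 0.2, (n, p)),
        sample_id=np.array([f"s{i}" for i in range(n)], dtype=object),
        alcohol=rng.uniform(3, 12, n),
        wort=rng.uniform(8, 24, n),
        class_label=classes,
    )


@pytest.fixture
def small_ds():
    return random_dataset()
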