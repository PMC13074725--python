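"""Data model and file I/O for NIR spectral datasets with aligned targets.

A :class:`SpectralDataset` holds an absorbance matrix on a shared wavelength
grid together with up to three aligned target vectors: alcohol content
(% vol), original wort concentration (degrees Plato) and a beer class label
(craft / industrial / non_fermented).  Datasets are serialized as a single
wide CSV: ``sample_id``, target columns, then one column per wavelength named
by its nm value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CLASS_LABELS = ("craft", "industrial", "non_fermented")

#: significant digits used when serializing absorbance values
_FLOAT_DIGITS = 9

_TARGET_COLS = ("alcohol", "wort", "class")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength grid needs at least 2 values")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    @classmethod
    def uniform(cls, start: float = 900.0, stop: float = 1700.0,
                n: int = 228) -> "WavelengthGrid":
        """The instrument's uniform grid: 228 points over 900-1700 nm."""
        return cls(np.linspace(start, stop, n))


@dataclass
class SpectralDataset:
    """Absorbance matrix plus aligned quantitative and categorical targets.

    Any of ``alcohol``, ``wort`` and ``class_label`` may be ``None`` (absent);
    present targets must align with the rows of ``absorbance``.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_id: np.ndarray
    alcohol: np.ndarray | None = None
    wort: np.ndarray | None = None
    class_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if p != len(self.grid):
            raise ValueError(
                f"absorbance has {p} columns but grid has {len(self.grid)}")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite entries")
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if self.sample_id.shape != (n,):
            raise ValueError("sample_id must align with absorbance rows")
        if len(set(self.sample_id)) != n:
            raise ValueError("duplicated sample id")
        for name in ("alcohol", "wort"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,) or not np.all(np.isfinite(v)):
                    raise ValueError(f"{name} target invalid")
                setattr(self, name, v)
        if self.class_label is not None:
            lab = np.asarray(self.class_label, dtype=object)
            if lab.shape != (n,):
                raise ValueError("class_label must align with rows")
            bad = set(lab) - set(CLASS_LABELS)
            if bad:
                raise ValueError(f"unknown class labels: {sorted(bad)}")
            self.class_label = lab

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def has_targets(self, *names: str) -> bool:
        mapping = {"alcohol": self.alcohol, "wort": self.wort,
                   "classify": self.class_label}
        return all(mapping[n] is not None for n in names)

    def target(self, task: str) -> np.ndarray:
        """Target vector for ``task`` in {alcohol, wort, classify}."""
        value = {"alcohol": self.alcohol, "wort": self.wort,
                 "classify": self.class_label}[task]
        if value is None:
            raise ValueError(f"dataset has no target for task {task!r}")
        return value


@dataclass
class DatasetSplit:
    """Disjoint calibration / validation / test index sets."""

    calibration: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("calibration", "validation", "test"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        parts = [set(self.calibration), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split index sets overlap")

    def save(self, path: str | Path) -> None:
        payload = {
            "calibration": self.calibration.tolist(),
            "validation": self.validation.tolist(),
            "test": self.test.tolist(),
            "seed": self.seed,
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DatasetSplit":
        payload = json.loads(Path(path).read_text())
        return cls(payload["calibration"], payload["validation"],
                   payload["test"], payload.get("seed"),
                   payload.get("meta", {}))


def _wavelength_col(nm: float) -> str:
    return repr(float(nm))  # shortest exact decimal representation


def write_dataset(ds: SpectralDataset, path: str | Path) -> None:
    """Serialize ``ds`` as a wide CSV readable by :func:`read_dataset`.

    Targets are written exactly; absorbance with 9 significant digits.
    Absent targets omit their column entirely.
    """
    if ds.n_samples == 0:
        raise ValueError("empty dataset")
    data: dict[str, object] = {"sample_id": ds.sample_id}
    if ds.alcohol is not None:
        data["alcohol"] = ds.alcohol
    if ds.wort is not None:
        data["wort"] = ds.wort
    if ds.class_label is not None:
        data["class"] = ds.class_label
    fmt = f".{_FLOAT_DIGITS}g"
    for j, nm in enumerate(ds.grid.values):
        # absorbance at fixed significant digits; targets keep full precision
        data[_wavelength_col(nm)] = [format(v, fmt)
                                     for v in ds.absorbance[:, j]]
    frame = pd.DataFrame(data)
    frame.to_csv(path, index=False)


def read_dataset(path: str | Path) -> SpectralDataset:
    """Read a wide-CSV spectral dataset.

    The header encodes the wavelength grid: every column whose name parses as
    a number is a wavelength; the remainder must be ``sample_id`` and the
    optional target columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"sample_id": str, "class": str},
                        float_precision="round_trip")
    wl_cols = []
    for col in frame.columns:
        if col == "sample_id" or col in _TARGET_COLS:
            continue
        try:
            wl_cols.append((float(col), col))
        except ValueError as exc:
            raise ValueError(f"unrecognized column {col!r}") from exc
    if len(wl_cols) < 2:
        raise ValueError("fewer than 2 wavelength columns")
    grid = WavelengthGrid(np.array([nm for nm, _ in wl_cols]))
    absorb = frame[[c for _, c in wl_cols]].to_numpy()
    try:
        absorb = absorb.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError("non-numeric absorbance") from exc
    if not np.all(np.isfinite(absorb)):
        raise ValueError("non-numeric absorbance")
    return SpectralDataset(
        grid=grid,
        absorbance=absorb,
        sample_id=frame["sample_id"].to_numpy(dtype=object),
        alcohol=frame["alcohol"].to_numpy() if "alcohol" in frame else None,
        wort=frame["wort"].to_numpy() if "wort" in frame else None,
        class_label=(frame["class"].to_numpy(dtype=object)
                     if "class" in frame else None),
    )


def subset(ds: SpectralDataset, indices: Sequence[int] | Iterable[int]
           ) -> SpectralDataset:
    """Row-select a dataset; order follows ``indices``, grid unchanged."""
    idx = np.asarray(list(indices), dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    if idx.min() < 0 or idx.max() >= ds.n_samples:
        raise IndexError("subset index out of range")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError("duplicated index in subset")
    pick = lambda v: None if v is None else v[idx]
    return SpectralDataset(
        grid=ds.grid,
        absorbance=ds.absorbance[idx],
        sample_id=ds.sample_id[idx],
        alcohol=pick(ds.alcohol),
        wort=pick(ds.wort),
        class_label=pick(ds.class_label),
    )
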