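"""Solubility dataset container, CSV I/O, splitting and feature scaling.

The study data are isothermal/isobaric measurements of a drug's mole-fraction
solubility in supercritical CO2 on a temperature x pressure grid.  A dataset
is held as a small pandas DataFrame with the fixed columns ``temperature_K``,
``pressure_bar`` and ``solubility``; the bundled ketoprofen table (28 rows,
four temperatures x seven pressures) ships inside the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

__all__ = [
    "COLUMNS",
    "SolubilityDataset",
    "DataSplit",
    "load_dataset",
    "write_dataset",
    "split_dataset",
    "fit_scaler",
    "apply_scaler",
]

COLUMNS = ("temperature_K", "pressure_bar", "solubility")

_BUNDLED_NAME = "ketoprofen_scco2.csv"


class DatasetValidationError(ValueError):
    """Raised when a solubility table violates the dataset invariants."""


@dataclass
class SolubilityDataset:
    """An ordered collection of (T [K], P [bar], solubility) records.

    Solubility is a dimensionless mole fraction and must be strictly
    positive; (T, P) pairs must be unique.
    """

    frame: pd.DataFrame
    name: str = "unnamed"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """(n, 2) feature matrix of raw temperature and pressure."""
        return self.frame[["temperature_K", "pressure_bar"]].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        """(n,) strictly positive solubility targets."""
        return self.frame["solubility"].to_numpy(float)

    @property
    def temperatures(self) -> np.ndarray:
        return np.unique(self.frame["temperature_K"].to_numpy(float))

    @property
    def pressures(self) -> np.ndarray:
        return np.unique(self.frame["pressure_bar"].to_numpy(float))


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetValidationError(f"missing column(s): {missing}; expected {COLUMNS}")
    frame = frame.loc[:, list(COLUMNS)].reset_index(drop=True)
    for col in COLUMNS:
        values = pd.to_numeric(frame[col], errors="coerce")
        if values.isna().any():
            bad = frame.index[values.isna()].tolist()
            raise DatasetValidationError(f"non-numeric cell(s) in column {col!r} at rows {bad}")
        frame[col] = values.astype(float)
    if len(frame) == 0:
        raise DatasetValidationError("dataset is empty")
    if (frame["solubility"] <= 0).any():
        bad = frame.index[frame["solubility"] <= 0].tolist()
        raise DatasetValidationError(f"solubility must be > 0 (mole fraction); rows {bad}")
    if (frame["temperature_K"] <= 0).any() or (frame["pressure_bar"] <= 0).any():
        raise DatasetValidationError("temperature and pressure must be > 0")
    dup = frame.duplicated(subset=["temperature_K", "pressure_bar"])
    if dup.any():
        raise DatasetValidationError(
            f"duplicate (temperature, pressure) pairs at rows {frame.index[dup].tolist()}"
        )
    return frame


def load_dataset(source: str | Path = "bundled") -> SolubilityDataset:
    """Read a solubility CSV, or the packaged ketoprofen/scCO2 table.

    Parameters
    ----------
    source:
        ``"bundled"`` for the in-package 28-row ketoprofen dataset, else a
        path to a CSV with header ``temperature_K,pressure_bar,solubility``
        (period decimal separator; scientific notation accepted).
    """
    if str(source) == "bundled":
        ref = resources.files("scfsol.data").joinpath(_BUNDLED_NAME)
        with resources.as_file(ref) as path:
            frame = pd.read_csv(path)
        return SolubilityDataset(
            frame,
            name="ketoprofen_scco2",
            provenance="bundled 28-row ketoprofen solubility table (4 temperatures x 7 pressures)",
        )
    path = Path(source)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DatasetValidationError(f"could not parse {path}: {exc}") from exc
    return SolubilityDataset(frame, name=path.stem, provenance=str(path))


def write_dataset(ds: SolubilityDataset, path: str | Path) -> Path:
    """Write the dataset CSV; ``load_dataset`` round-trips it exactly."""
    path = Path(path)
    ds.frame.to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class DataSplit:
    """A reproducible random train/test partition of a dataset's row indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    fraction_test: float

    def __post_init__(self) -> None:
        overlap = np.intersect1d(self.train_indices, self.test_indices)
        if overlap.size:
            raise ValueError("train and test indices overlap")


def split_dataset(
    ds: SolubilityDataset, fraction_test: float = 0.2, seed: int = 0
) -> DataSplit:
    """Randomly partition rows into train/test subsets.

    The test size is round-half-up of ``fraction_test * n``.  The same seed
    always yields the same index sets.
    """
    n = len(ds)
    if not 0.0 < fraction_test < 1.0:
        raise ValueError("fraction_test must be in (0, 1)")
    if n < 5:
        raise ValueError("need at least 5 records to split")
    n_test = int(math.floor(fraction_test * n + 0.5))
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"fraction_test={fraction_test} leaves an empty train or test subset for n={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return DataSplit(
        train_indices=np.sort(perm[n_test:]),
        test_indices=np.sort(perm[:n_test]),
        seed=seed,
        fraction_test=fraction_test,
    )


@dataclass
class FeatureScaler:
    """Zero-mean / unit-spread affine scaler for the (T, P) features."""

    center: np.ndarray
    scale: np.ndarray
    _sk: StandardScaler = field(repr=False, default=None)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.center) / self.scale

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, float) * self.scale + self.center


def fit_scaler(ds: SolubilityDataset) -> FeatureScaler:
    """Fit a standardizing scaler to the dataset's (T, P) columns."""
    sk = StandardScaler().fit(ds.X)
    if np.any(sk.scale_ == 0) or np.any(~np.isfinite(1.0 / sk.scale_)):
        raise ValueError("constant feature: zero spread cannot be standardized")
    # StandardScaler maps a truly constant column to scale 1; reject it explicitly
    if np.any(ds.X.std(axis=0) == 0):
        raise ValueError("constant feature: zero spread cannot be standardized")
    return FeatureScaler(center=sk.mean_.copy(), scale=sk.scale_.copy(), _sk=sk)


def apply_scaler(scaler: FeatureScaler, X: np.ndarray) -> np.ndarray:
    """Standardize a raw (T, P) feature matrix with a fitted scaler."""
    return scaler.transform(X)
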