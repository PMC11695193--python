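"""In-memory containers shared across the pipeline.

The pipeline moves data through three representations: gridded raster
stacks (one per variable per season), per-county zonal-mean time series,
and model-ready sample tensors.  County-year yield tables travel as plain
:class:`pandas.DataFrame` objects with the schema
``county_id, year, yield_kg_ha[, yield_true_kg_ha]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical feature ordering used whenever a full feature set is assembled.
FEATURE_ORDER = ("EVI", "LAI", "SIF", "T2m", "Tmn", "Tmx", "Pre", "U10m", "V10m")


@dataclass
class GridStack:
    """A (time x rows x cols) raster stack for one variable.

    Parameters
    ----------
    variable : str
        Variable name, e.g. ``"EVI"`` or ``"T2m"``.
    values : ndarray, shape (T, R, C)
        Raster frames.  ``nodata`` cells carry the sentinel value.
    start_dates : ndarray of int
        Day-of-season on which each frame (or composite window) starts.
        Strictly increasing.
    nodata : float
        Sentinel marking invalid cells (default NaN).
    """

    variable: str
    values: np.ndarray
    start_dates: np.ndarray
    nodata: float = np.nan

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.start_dates = np.asarray(self.start_dates, dtype=int)
        if self.values.ndim != 3:
            raise ValueError(f"values must be (T, R, C); got shape {self.values.shape}")
        if len(self.start_dates) != self.values.shape[0]:
            raise ValueError("start_dates length must equal the number of frames")
        if len(self.start_dates) > 1 and not np.all(np.diff(self.start_dates) > 0):
            raise ValueError("start_dates must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def mask_invalid(self) -> np.ndarray:
        """Boolean array, True where a cell is valid (not nodata)."""
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata


@dataclass
class CountyMap:
    """County labels and cropland mask on a common grid.

    ``county_ids`` assigns every pixel exactly one integer label in
    ``[0, n_counties)``; ``cropland`` marks pixels used for zonal means.
    """

    county_ids: np.ndarray
    cropland: np.ndarray

    def __post_init__(self) -> None:
        self.county_ids = np.asarray(self.county_ids, dtype=int)
        self.cropland = np.asarray(self.cropland, dtype=bool)
        if self.county_ids.shape != self.cropland.shape:
            raise ValueError("county_ids and cropland must share grid dims")
        if self.county_ids.min() < 0:
            raise ValueError("county labels must be nonnegative")

    @property
    def n_counties(self) -> int:
        return int(self.county_ids.max()) + 1

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.county_ids.shape


@dataclass
class CountySeries:
    """Zonal-mean composite time series for one county-year.

    values is a (T x F) matrix; column order is ``feature_names``.
    """

    county_id: int
    year: int
    values: np.ndarray
    feature_names: tuple[str, ...]
    composite_dates: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = tuple(self.feature_names)
        self.composite_dates = np.asarray(self.composite_dates, dtype=int)
        T, F = self.values.shape
        if F != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")
        if T != len(self.composite_dates):
            raise ValueError("composite_dates must match the number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"county {self.county_id} year {self.year}: series has missing cells"
            )

    def select(self, features: tuple[str, ...]) -> np.ndarray:
        """Return the (T x len(features)) submatrix in the requested order."""
        idx = [self.feature_names.index(f) for f in features]
        return self.values[:, idx]


@dataclass
class SampleSet:
    """Model-ready tensor of N samples x T composites x F features.

    Targets are yields in kg/ha.  ``y_true`` optionally carries the
    noise-free generating yields (known only for synthetic scenes), which
    pins down the best achievable skill on the scene.
    """

    X: np.ndarray
    y: np.ndarray
    county_ids: np.ndarray
    years: np.ndarray
    feature_names: tuple[str, ...]
    composite_dates: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    y_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.county_ids = np.asarray(self.county_ids, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.feature_names = tuple(self.feature_names)
        if self.X.ndim != 3:
            raise ValueError("X must be (N, T, F)")
        n = self.X.shape[0]
        if not (len(self.y) == len(self.county_ids) == len(self.years) == n):
            raise ValueError("y, county_ids and years must all have length N")
        if self.X.shape[2] != len(self.feature_names):
            raise ValueError("feature_names must match F")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_composites(self) -> int:
        return self.X.shape[1]

    def take(self, idx) -> "SampleSet":
        """Subset samples by integer index array (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return SampleSet(
            X=self.X[idx],
            y=self.y[idx],
            county_ids=self.county_ids[idx],
            years=self.years[idx],
            feature_names=self.feature_names,
            composite_dates=self.composite_dates,
            y_true=None if self.y_true is None else self.y_true[idx],
        )

    def truncate(self, n_composites: int) -> "SampleSet":
        """Keep only the first ``n_composites`` composites of each sample."""
        if not 1 <= n_composites <= self.n_composites:
            raise ValueError("n_composites out of range")
        return SampleSet(
            X=self.X[:, :n_composites, :],
            y=self.y,
            county_ids=self.county_ids,
            years=self.years,
            feature_names=self.feature_names,
            composite_dates=self.composite_dates[:n_composites],
            y_true=self.y_true,
        )

    def select_features(self, features) -> "SampleSet":
        """Project onto a feature subset, in the given order."""
        features = tuple(features)
        unknown = [f for f in features if f not in self.feature_names]
        if unknown:
            raise KeyError(f"unknown features: {unknown}")
        idx = [self.feature_names.index(f) for f in features]
        return SampleSet(
            X=self.X[:, :, idx],
            y=self.y,
            county_ids=self.county_ids,
            years=self.years,
            feature_names=features,
            composite_dates=self.composite_dates,
            y_true=self.y_true,
        )


def validate_yield_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a county-year yield table and return it unchanged.

    Requires columns ``county_id, year, yield_kg_ha``; one row per
    county-year; strictly positive yields.
    """
    required = {"county_id", "year", "yield_kg_ha"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"yield table missing columns: {sorted(missing)}")
    if table.duplicated(["county_id", "year"]).any():
        raise ValueError("yield table has duplicate county-year rows")
    if (table["yield_kg_ha"] <= 0).any():
        raise ValueError("yields must be positive")
    return table


def filter_min_yield(table: pd.DataFrame, threshold: float = 3000.0) -> pd.DataFrame:
    """Drop county-years below a yield threshold (kg/ha).

    Study-region screens commonly retain only counties with yields above
    3000 kg/ha; this applies the same optional filter.
    """
    return table.loc[table["yield_kg_ha"] > threshold].reset_index(drop=True)
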