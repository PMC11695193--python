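"""Preparation chain for multisource composites.

Implements the standard raster-to-sample pipeline: Savitzky-Golay
smoothing of vegetation-index series, maximum-value compositing (MVC) of
fine-cadence SIF frames to 8-day windows, 8-day aggregated averaging of
daily climate grids, bilinear resampling, cropland-masked county zonal
means, [0, 1] min-max normalization with training-only statistics, SPEI
drought classification, and assembly of model-ready sample tensors.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .containers import CountyMap, CountySeries, GridStack, SampleSet, validate_yield_table

logger = logging.getLogger(__name__)

__all__ = [
    "DroughtClass",
    "NormalizationParams",
    "EmptyCountyError",
    "sg_smooth",
    "mvc_composite",
    "aggregate_climate",
    "resample_bilinear",
    "mask_and_average",
    "normalize_minmax",
    "denormalize_minmax",
    "classify_spei",
    "build_samples",
]


class EmptyCountyError(ValueError):
    """Raised when a county has no cropland pixels to average over."""

    def __init__(self, county_ids: Sequence[int]):
        self.county_ids = list(county_ids)
        super().__init__(f"counties with no masked pixels: {self.county_ids}")


# ---------------------------------------------------------------------------
# smoothing / compositing / aggregation


def sg_smooth(series: np.ndarray, window: int = 9, order: int = 2, axis: int = -1) -> np.ndarray:
    """Savitzky-Golay smoothing (default window 9, polynomial order 2).

    Each interior point is replaced by the value, at its own position, of
    the least-squares polynomial of the given order fitted over the
    centered window.  Near the edges the polynomial is fitted to the
    nearest full window and evaluated at the edge position, so the output
    keeps the input length.

    Parameters
    ----------
    series : array_like
        Input values; smoothing runs along ``axis``.
    window : odd int
        Window length in samples.
    order : int
        Polynomial order, must be < window.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be smaller than window")
    if series.shape[axis] < window:
        raise ValueError(
            f"series length {series.shape[axis]} shorter than window {window}"
        )
    return savgol_filter(series, window_length=window, polyorder=order, axis=axis, mode="interp")


def _window_starts(dates: np.ndarray, window_days: int, starts: np.ndarray | None) -> np.ndarray:
    if starts is not None:
        return np.asarray(starts, dtype=int)
    first, last = int(dates[0]), int(dates[-1])
    return np.arange(first, last + 1, window_days, dtype=int)


def mvc_composite(
    frames: GridStack,
    window_days: int = 8,
    composite_starts: np.ndarray | None = None,
) -> GridStack:
    """Maximum-value compositing of fine-cadence frames into windows.

    Per pixel and window ``[start, start + window_days)`` the output is
    the maximum over all frames whose date falls in the window; nodata
    cells are ignored unless every contributing cell is nodata.  A window
    containing no frames at all is an error.
    """
    dates = frames.start_dates
    starts = _window_starts(dates, window_days, composite_starts)
    valid = frames.mask_invalid()
    vals = np.where(valid, frames.values, -np.inf)

    out = np.empty((len(starts),) + frames.grid_shape)
    for w, s in enumerate(starts):
        in_win = (dates >= s) & (dates < s + window_days)
        if not in_win.any():
            raise ValueError(
                f"no frames fall in composite window [{s}, {s + window_days})"
            )
        best = vals[in_win].max(axis=0)
        out[w] = np.where(np.isneginf(best), np.nan, best)
    return GridStack(frames.variable, out, starts, nodata=np.nan)


def aggregate_climate(
    daily: GridStack,
    window_days: int = 8,
    composite_starts: np.ndarray | None = None,
) -> GridStack:
    """8-day aggregated averaging of a daily climate stack.

    Arithmetic mean of the daily values falling in each composite window
    (applied uniformly to all climate variables, precipitation included).
    """
    dates = daily.start_dates
    starts = _window_starts(dates, window_days, composite_starts)
    out = np.empty((len(starts),) + daily.grid_shape)
    for w, s in enumerate(starts):
        in_win = (dates >= s) & (dates < s + window_days)
        if not in_win.any():
            raise ValueError(f"no days fall in aggregation window [{s}, {s + window_days})")
        out[w] = daily.values[in_win].mean(axis=0)
    return GridStack(daily.variable, out, starts, nodata=daily.nodata)


def resample_bilinear(grid: np.ndarray, target_rows: int, target_cols: int) -> np.ndarray:
    """Bilinear resampling on cell-center coordinates.

    Source and target extents coincide; target cell centers are mapped
    linearly into source pixel coordinates and interpolated from the four
    surrounding source cell centers (edge cells clamp).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or min(grid.shape) < 2:
        raise ValueError("source grid must be 2-D with dims >= 2")
    if target_rows < 1 or target_cols < 1:
        raise ValueError("target dims must be >= 1")
    sr, sc = grid.shape
    # cell-center mapping: target center (i+0.5)/tr of the extent
    r = (np.arange(target_rows) + 0.5) * sr / target_rows - 0.5
    c = (np.arange(target_cols) + 0.5) * sc / target_cols - 0.5
    r = np.clip(r, 0, sr - 1)
    c = np.clip(c, 0, sc - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, sr - 1)
    c1 = np.minimum(c0 + 1, sc - 1)
    fr = (r - r0)[:, None]
    fc = (c - c0)[None, :]
    g00 = grid[np.ix_(r0, c0)]
    g01 = grid[np.ix_(r0, c1)]
    g10 = grid[np.ix_(r1, c0)]
    g11 = grid[np.ix_(r1, c1)]
    return (
        g00 * (1 - fr) * (1 - fc)
        + g01 * (1 - fr) * fc
        + g10 * fr * (1 - fc)
        + g11 * fr * fc
    )


# ---------------------------------------------------------------------------
# zonal statistics


def mask_and_average(stack: GridStack, county_map: CountyMap) -> np.ndarray:
    """Cropland-masked county zonal means.

    Returns a (n_counties x T) array: for each county and composite, the
    mean over pixels that are both inside the county and cropland-true.
    Counties with zero masked pixels raise :class:`EmptyCountyError`
    rather than being silently dropped.
    """
    if stack.grid_shape != county_map.grid_shape:
        raise ValueError("stack and county map must share grid dims")
    n = county_map.n_counties
    labels = county_map.county_ids.ravel()
    mask = county_map.cropland.ravel()
    counts = np.bincount(labels[mask], minlength=n)
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise EmptyCountyError(empty.tolist())

    T = stack.n_frames
    out = np.empty((n, T))
    flat = stack.values.reshape(T, -1)
    for t in range(T):
        sums = np.bincount(labels[mask], weights=flat[t, mask], minlength=n)
        out[:, t] = sums / counts
    return out


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizationParams:
    """Per-feature min/max learned on training samples only."""

    minima: np.ndarray
    maxima: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.minima = np.asarray(self.minima, dtype=float)
        self.maxima = np.asarray(self.maxima, dtype=float)
        self.feature_names = tuple(self.feature_names)
        if np.any(self.maxima < self.minima):
            raise ValueError("per-feature max must be >= min")


def normalize_minmax(
    X: np.ndarray,
    params: NormalizationParams | None = None,
    feature_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, NormalizationParams]:
    """Min-max scale features to [0, 1].

    When ``params`` is None the per-feature min/max are computed over the
    given (training) samples and returned for reuse; otherwise the frozen
    statistics are applied.  Values outside the training range clip to
    [0, 1].  A constant feature (max == min) maps to 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    F = X.shape[-1]
    if params is None:
        flat = X.reshape(-1, F)
        names = tuple(feature_names) if feature_names is not None else tuple(
            f"f{i}" for i in range(F)
        )
        params = NormalizationParams(flat.min(axis=0), flat.max(axis=0), names)
    elif len(params.minima) != F:
        raise ValueError("params feature count does not match input")

    span = params.maxima - params.minima
    degenerate = span == 0
    if degenerate.any():
        bad = [params.feature_names[i] for i in np.nonzero(degenerate)[0]]
        logger.warning("constant feature(s) %s mapped to 0 under min-max scaling", bad)
    safe = np.where(degenerate, 1.0, span)
    scaled = (X - params.minima) / safe
    scaled = np.where(degenerate, 0.0, scaled)
    return np.clip(scaled, 0.0, 1.0), params


def denormalize_minmax(X01: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Inverse of :func:`normalize_minmax` for in-range values."""
    return np.asarray(X01, dtype=float) * (params.maxima - params.minima) + params.minima


# ---------------------------------------------------------------------------
# drought classification


class DroughtClass(enum.Enum):
    """SPEI drought classes, from non-drought to extreme drought."""

    ND = "non-drought"
    MD1 = "moderate drought"
    MD2 = "middle drought"
    SD = "severe drought"
    ED = "extreme drought"

    @property
    def severity(self) -> int:
        return list(DroughtClass).index(self)


def classify_spei(spei: float) -> DroughtClass:
    """Classify an SPEI value into drought bands.

    ND for SPEI > -0.5; MD1 for -0.5 >= SPEI > -1; MD2 for -1 >= SPEI > -1.5;
    SD for -1.5 >= SPEI > -2; ED for SPEI <= -2.  Boundary values belong to
    the more severe (lower) class.
    """
    spei = float(spei)
    if not np.isfinite(spei):
        raise ValueError("SPEI must be finite")
    if spei > -0.5:
        return DroughtClass.ND
    if spei > -1.0:
        return DroughtClass.MD1
    if spei > -1.5:
        return DroughtClass.MD2
    if spei > -2.0:
        return DroughtClass.SD
    return DroughtClass.ED


# ---------------------------------------------------------------------------
# sample assembly


def build_samples(
    county_series: Iterable[CountySeries],
    yields: pd.DataFrame,
    features: Sequence[str],
) -> SampleSet:
    """Stack county-year series and join yields into a model-ready tensor.

    Features are taken in the declared order; county-years without a yield
    row are excluded with a log line.  Yields stay in kg/ha.
    """
    validate_yield_table(yields)
    features = tuple(features)
    series = list(county_series)
    if not series:
        raise ValueError("no county series supplied")
    for f in features:
        if f not in series[0].feature_names:
            raise KeyError(f"unknown feature {f!r}")

    has_truth = "yield_true_kg_ha" in yields.columns
    ytab = yields.set_index(["county_id", "year"])

    X, y, cids, yrs, ytrue = [], [], [], [], []
    for s in series:
        key = (s.county_id, s.year)
        if key not in ytab.index:
            logger.info("excluding county %d year %d: no yield record", *key)
            continue
        X.append(s.select(features))
        row = ytab.loc[key]
        y.append(float(row["yield_kg_ha"]))
        if has_truth:
            ytrue.append(float(row["yield_true_kg_ha"]))
        cids.append(s.county_id)
        yrs.append(s.year)
    if not X:
        raise ValueError("no county-year overlaps between series and yields")

    return SampleSet(
        X=np.stack(X),
        y=np.array(y),
        county_ids=np.array(cids),
        years=np.array(yrs),
        feature_names=features,
        composite_dates=series[0].composite_dates,
        y_true=np.array(ytrue) if has_truth else None,
    )
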