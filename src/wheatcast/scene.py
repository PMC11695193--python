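"""Synthetic multi-year scene generator with a known yield process.

Emulates the statistical structure of a county-level winter-wheat study
region: 8-day vegetation composites (EVI, LAI) following double-logistic
phenology, solar-induced chlorophyll fluorescence (SIF) emitted at 4-day
cadence (so compositing is a real step downstream), daily climate grids
with seasonal cycles, monthly SPEI, a Voronoi county partition with a
cropland mask, and county-year yields generated from growing-season
vegetation/climate integrals plus noise.

Day 0 is sowing (early October); harvest is day 248; a season is T = 31
eight-day composites.  Drought years attenuate SIF inside a spring stress
window and push the in-window monthly SPEI into a configured drought band,
so the yield penalty of a drought is routed through SIF — the feature the
downstream analyses probe.

The noise-free generating yield is recorded next to the noisy one, which
pins down the best achievable ("oracle") skill on a scene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import FEATURE_ORDER, CountyMap, CountySeries, GridStack
from .preprocess import aggregate_climate, mask_and_average, mvc_composite, sg_smooth

logger = logging.getLogger(__name__)

CLIMATE_VARS = ("T2m", "Tmn", "Tmx", "Pre", "U10m", "V10m")

# fixed per-stream codes so every (seed, year) pair owns independent substreams
_STREAM_REGION = 101
_STREAM_VEG = 102
_STREAM_CLIMATE = 103
_STREAM_SPEI = 104
_STREAM_YIELD = 105


@dataclass
class ClimateConfig:
    """Seasonal-cycle parameters for the daily climate generator.

    Temperatures in deg C, precipitation in mm/day, wind in m/s.  The
    coldest day sits in mid-January (day ~107 from an early-October day 0).
    """

    t2m_mean: float = 12.0
    t2m_amplitude: float = 13.0
    coldest_day: int = 107
    year_anomaly_sd: float = 0.8  # per-year additive temperature shift
    diurnal_spread: float = 4.0  # Tmx - T2m and T2m - Tmn baseline
    noise_sd_temp: float = 1.5
    precip_mean: float = 2.0
    precip_sd: float = 3.0
    wind_mean: float = 2.0
    wind_amplitude: float = 1.0
    noise_sd_wind: float = 0.8


@dataclass
class YieldCoefficients:
    """Weights of the linear yield-generating process (kg/ha units).

    yield = intercept + sif * SUM(SIF, critical window)
          + evi * SUM(EVI, season) + gdd * GDD
          - heat * heat_exceedance - drought * max(0, -mean SPEI) + noise
    """

    intercept: float = 1500.0
    sif: float = 700.0
    evi: float = 200.0
    gdd: float = 0.5
    heat: float = 10.0
    drought: float = 800.0
    t_base: float = 0.0  # GDD base temperature, deg C
    t_hot: float = 28.0  # heat-stress threshold on Tmx, deg C


@dataclass
class SceneConfig:
    """Configuration of one synthetic study region.

    The critical window (composites 19-28, days 152-231, roughly early
    March to early May for a day-0 of October 1) is both where drought
    stress attenuates SIF and the window the yield process integrates
    SIF over.
    """

    n_years: int = 10
    n_counties: int = 93
    grid_rows: int = 64
    grid_cols: int = 64
    composite_length_days: int = 8
    season_length_composites: int = 31
    cropland_fraction: float = 0.6
    noise_sd_veg: float = 0.02
    noise_sd_yield: float = 300.0
    drought_years: tuple[int, ...] = ()
    drought_severity: float = 1.0
    drought_class: str = "SD"
    drought_window: tuple[int, int] = (19, 29)  # half-open, composite indices
    county_effect_sd: float = 0.20  # relative sd of county-year amplitude effects
    phenology_shift_sd: float = 5.0  # sd (days) of county-year inflection shifts
    veg_base: float = 0.08
    veg_amplitude: float = 0.45
    greenup_day: float = 140.0
    senescence_day: float = 215.0
    greenup_rate: float = 0.07
    senescence_rate: float = 0.09
    sif_scale: float = 1.2
    light_base: float = 0.6
    light_amplitude: float = 0.4
    yield_coefficients: YieldCoefficients = field(default_factory=YieldCoefficients)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.season_length_composites < 2:
            raise ValueError("need at least 2 composites per season")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dims must be >= 1")
        if self.n_counties < 1:
            raise ValueError("need at least one county")
        if self.n_counties > self.grid_rows * self.grid_cols:
            raise ValueError("more counties than pixels")
        if not 0.0 <= self.cropland_fraction <= 1.0:
            raise ValueError("cropland_fraction must be in [0, 1]")
        if not 0.0 < self.drought_severity <= 1.0:
            raise ValueError("drought_severity must be in (0, 1]")
        if self.noise_sd_veg < 0 or self.noise_sd_yield < 0:
            raise ValueError("noise sds must be nonnegative")

    @property
    def season_days(self) -> int:
        return self.season_length_composites * self.composite_length_days

    @property
    def composite_starts(self) -> np.ndarray:
        return np.arange(self.season_length_composites) * self.composite_length_days

    def rng(self, stream: int, year: int = 0) -> np.random.Generator:
        """Seeded substream for one (year, stream) pair."""
        return np.random.default_rng([self.seed, year, stream])


def double_logistic(
    t: np.ndarray,
    base: float | np.ndarray,
    amplitude: float | np.ndarray,
    greenup_day: float | np.ndarray,
    greenup_rate: float | np.ndarray,
    senescence_day: float | np.ndarray,
    senescence_rate: float | np.ndarray,
) -> np.ndarray:
    """Double-logistic phenology curve over day-of-season t.

    v(t) = base + amp * [1/(1+exp(-r1 (t-t1))) - 1/(1+exp(-r2 (t-t2)))].
    """
    t = np.asarray(t, dtype=float)
    up = 1.0 / (1.0 + np.exp(-np.asarray(greenup_rate) * (t - np.asarray(greenup_day))))
    down = 1.0 / (1.0 + np.exp(-np.asarray(senescence_rate) * (t - np.asarray(senescence_day))))
    return np.asarray(base) + np.asarray(amplitude) * (up - down)


def lai_from_evi(evi: np.ndarray) -> np.ndarray:
    """Monotone LAI surrogate: 6 * EVI^1.2 clipped to [0, 7]."""
    return np.clip(6.0 * np.clip(evi, 0.0, None) ** 1.2, 0.0, 7.0)


def generate_region(config: SceneConfig) -> CountyMap:
    """Voronoi-like county partition plus a Bernoulli cropland mask.

    County seed pixels are drawn without replacement, so every county owns
    at least its own seed pixel; remaining pixels join the nearest seed
    (ties to the lowest county index).
    """
    rng = config.rng(_STREAM_REGION)
    R, C = config.grid_rows, config.grid_cols
    centers = rng.choice(R * C, size=config.n_counties, replace=False)
    cr, cc = np.divmod(centers, C)
    rr, cc_grid = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
    d2 = (rr[..., None] - cr) ** 2 + (cc_grid[..., None] - cc) ** 2
    labels = np.argmin(d2, axis=-1)
    cropland = rng.random((R, C)) < config.cropland_fraction
    if not cropland.any():
        logger.warning("cropland mask is empty; zonal means downstream will fail")
    return CountyMap(labels, cropland)


def _county_year_phenology(config: SceneConfig, year: int):
    """Per-county amplitude/timing random effects for one year."""
    rng = config.rng(_STREAM_VEG, year)
    n = config.n_counties
    amp = config.veg_amplitude * (1.0 + config.county_effect_sd * rng.standard_normal(n))
    amp = np.clip(amp, 0.05, None)
    t1 = config.greenup_day + config.phenology_shift_sd * rng.standard_normal(n)
    t2 = config.senescence_day + config.phenology_shift_sd * rng.standard_normal(n)
    return rng, amp, t1, t2


def generate_vegetation(
    config: SceneConfig, county_map: CountyMap, year: int
) -> dict[str, GridStack]:
    """EVI/LAI at composite cadence and SIF at 4-day cadence for one year.

    Each pixel follows its county's double-logistic curve; SIF is
    sif_scale * EVI * L(t) with a seasonal light term L, attenuated by
    ``drought_severity`` inside the stress window in drought years.
    Independent additive Gaussian noise (sd ``noise_sd_veg``) is applied
    to every emitted variable.
    """
    rng, amp, t1, t2 = _county_year_phenology(config, year)
    labels = county_map.county_ids
    amp_px = amp[labels]
    t1_px = t1[labels]
    t2_px = t2[labels]

    dates8 = config.composite_starts
    evi_clean = double_logistic(
        dates8[:, None, None], config.veg_base, amp_px, t1_px,
        config.greenup_rate, t2_px, config.senescence_rate,
    )
    lai_clean = lai_from_evi(evi_clean)

    step = config.composite_length_days // 2
    dates4 = np.arange(0, config.season_days, step)
    evi4 = double_logistic(
        dates4[:, None, None], config.veg_base, amp_px, t1_px,
        config.greenup_rate, t2_px, config.senescence_rate,
    )
    light = config.light_base + config.light_amplitude * np.sin(
        np.pi * dates4 / config.season_days
    )
    sif_clean = config.sif_scale * evi4 * light[:, None, None]
    if year in config.drought_years and config.drought_severity < 1.0:
        lo, hi = config.drought_window
        win = (dates4 >= lo * config.composite_length_days) & (
            dates4 < hi * config.composite_length_days
        )
        sif_clean[win] *= config.drought_severity

    sd = config.noise_sd_veg
    evi = evi_clean + sd * rng.standard_normal(evi_clean.shape)
    lai = lai_clean + sd * rng.standard_normal(lai_clean.shape)
    sif = sif_clean + sd * rng.standard_normal(sif_clean.shape)
    return {
        "EVI": GridStack("EVI", evi, dates8),
        "LAI": GridStack("LAI", lai, dates8),
        "SIF": GridStack("SIF", sif, dates4),
    }


def generate_climate(config: SceneConfig, year: int) -> dict[str, GridStack]:
    """Daily climate grids for one season.

    Sinusoidal seasonal cycles plus noise; Tmn <= T2m <= Tmx is enforced
    pointwise and precipitation is rectified to be nonnegative.
    """
    rng = config.rng(_STREAM_CLIMATE, year)
    cc = config.climate
    R, C = config.grid_rows, config.grid_cols
    days = np.arange(config.season_days)
    anomaly = cc.year_anomaly_sd * rng.standard_normal()

    cycle = cc.t2m_mean + anomaly - cc.t2m_amplitude * np.cos(
        2.0 * np.pi * (days - cc.coldest_day) / 365.0
    )
    shape = (len(days), R, C)
    t2m = cycle[:, None, None] + cc.noise_sd_temp * rng.standard_normal(shape)
    spread_hi = np.abs(cc.diurnal_spread + cc.noise_sd_temp * rng.standard_normal(shape))
    spread_lo = np.abs(cc.diurnal_spread + cc.noise_sd_temp * rng.standard_normal(shape))
    tmx = np.maximum(t2m + spread_hi, t2m)
    tmn = np.minimum(t2m - spread_lo, t2m)

    pre = np.clip(cc.precip_mean + cc.precip_sd * rng.standard_normal(shape), 0.0, None)
    wind_cycle = cc.wind_amplitude * np.sin(2.0 * np.pi * days / 365.0)
    u10 = cc.wind_mean + wind_cycle[:, None, None] + cc.noise_sd_wind * rng.standard_normal(shape)
    v10 = wind_cycle[:, None, None] + cc.noise_sd_wind * rng.standard_normal(shape)

    arrays = {"T2m": t2m, "Tmn": tmn, "Tmx": tmx, "Pre": pre, "U10m": u10, "V10m": v10}
    return {k: GridStack(k, v, days) for k, v in arrays.items()}


_SPEI_BANDS = {"MD1": (-1.0, -0.5), "MD2": (-1.5, -1.0), "SD": (-2.0, -1.5), "ED": (-2.8, -2.0)}


def generate_spei(config: SceneConfig, year: int) -> np.ndarray:
    """Monthly SPEI for the 8-month season (October through May).

    Non-drought months draw from Normal(0.2, 0.3).  In drought years the
    months overlapping the stress window draw uniformly inside the band of
    the configured drought class (e.g. severe drought = (-2, -1.5]).
    """
    rng = config.rng(_STREAM_SPEI, year)
    n_months = 8
    spei = rng.normal(0.2, 0.3, size=n_months)
    if year in config.drought_years:
        if config.drought_class not in _SPEI_BANDS:
            raise ValueError(f"unknown drought class {config.drought_class!r}")
        lo, hi = _SPEI_BANDS[config.drought_class]
        month_days = config.season_days / n_months
        w0, w1 = config.drought_window
        d0, d1 = w0 * config.composite_length_days, w1 * config.composite_length_days
        for m in range(n_months):
            if m * month_days < d1 and (m + 1) * month_days > d0:
                spei[m] = rng.uniform(lo, hi)
    return spei


def drought_months(config: SceneConfig) -> np.ndarray:
    """Indices of season months overlapping the drought stress window."""
    n_months = 8
    month_days = config.season_days / n_months
    w0, w1 = config.drought_window
    d0, d1 = w0 * config.composite_length_days, w1 * config.composite_length_days
    return np.array(
        [m for m in range(n_months) if m * month_days < d1 and (m + 1) * month_days > d0]
    )


def county_integrals(
    veg: dict[str, GridStack],
    climate: dict[str, GridStack],
    spei: np.ndarray,
    county_map: CountyMap,
    config: SceneConfig,
) -> pd.DataFrame:
    """Deterministic per-county seasonal integrals driving the yield process.

    Returns one row per county with SUM(SIF) over the critical window
    (8-day maximum-value composites of the emitted 4-day frames),
    SUM(EVI) over the season, growing degree days, heat exceedance and
    the drought penalty max(0, -mean SPEI).
    """
    yc = config.yield_coefficients
    sif8 = mvc_composite(
        veg["SIF"], config.composite_length_days, composite_starts=config.composite_starts
    )
    sif_means = mask_and_average(sif8, county_map)
    w0, w1 = config.drought_window
    sif_crit = sif_means[:, w0:w1].sum(axis=1)

    evi_means = mask_and_average(veg["EVI"], county_map)
    evi_all = evi_means.sum(axis=1)

    t2m = mask_and_average(climate["T2m"], county_map)
    tmx = mask_and_average(climate["Tmx"], county_map)
    gdd = np.maximum(t2m - yc.t_base, 0.0).sum(axis=1)
    heat = np.maximum(tmx - yc.t_hot, 0.0).sum(axis=1)
    dpen = max(0.0, -float(np.mean(spei)))

    return pd.DataFrame(
        {
            "county_id": np.arange(county_map.n_counties),
            "sif_critical": sif_crit,
            "evi_season": evi_all,
            "gdd": gdd,
            "heat_exceedance": heat,
            "drought_penalty": dpen,
        }
    )


def yield_from_integrals(integrals: pd.DataFrame, coeffs: YieldCoefficients) -> np.ndarray:
    """Noise-free yield (kg/ha) as a linear combination of the integrals."""
    return (
        coeffs.intercept
        + coeffs.sif * integrals["sif_critical"].to_numpy()
        + coeffs.evi * integrals["evi_season"].to_numpy()
        + coeffs.gdd * integrals["gdd"].to_numpy()
        - coeffs.heat * integrals["heat_exceedance"].to_numpy()
        - coeffs.drought * integrals["drought_penalty"].to_numpy()
    )


def compute_true_yield(
    veg: dict[str, GridStack],
    climate: dict[str, GridStack],
    spei: np.ndarray,
    county_map: CountyMap,
    config: SceneConfig,
    year: int,
) -> pd.DataFrame:
    """County-year yield table for one season.

    Adds Normal(0, noise_sd_yield) noise to the deterministic yield;
    nonpositive noisy yields are resampled (at most 10 retries, logged).
    Both the noisy and the noise-free yield are recorded.
    """
    integrals = county_integrals(veg, climate, spei, county_map, config)
    clean = yield_from_integrals(integrals, config.yield_coefficients)
    rng = config.rng(_STREAM_YIELD, year)
    noisy = clean + rng.normal(0.0, config.noise_sd_yield, size=len(clean))
    for _ in range(10):
        bad = noisy <= 0
        if not bad.any():
            break
        logger.info("resampling %d nonpositive yields in year %d", int(bad.sum()), year)
        noisy[bad] = clean[bad] + rng.normal(0.0, config.noise_sd_yield, size=int(bad.sum()))
    else:
        noisy = np.maximum(noisy, 1.0)
        logger.warning("capped nonpositive yields after 10 retries in year %d", year)
    return pd.DataFrame(
        {
            "county_id": integrals["county_id"],
            "year": year,
            "yield_kg_ha": noisy,
            "yield_true_kg_ha": clean,
        }
    )


@dataclass
class SceneDataset:
    """A fully preprocessed synthetic scene: series, yields, geography."""

    config: SceneConfig
    county_map: CountyMap
    county_series: list[CountySeries]
    yields: pd.DataFrame


def simulate_county_dataset(config: SceneConfig, smooth_vegetation: bool = True) -> SceneDataset:
    """Generate a scene and run the full preparation chain, year by year.

    For each year: generate rasters, Savitzky-Golay-smooth EVI/LAI
    pixelwise, composite 4-day SIF to 8 days by MVC, aggregate daily
    climate to the composite windows by averaging, then reduce everything
    to cropland-masked county means.  Raw (unsmoothed) stacks drive the
    yield process, mirroring the fact that real yields do not depend on
    our smoothing choices.
    """
    county_map = generate_region(config)
    starts = config.composite_starts
    series: list[CountySeries] = []
    tables = []
    for year in range(config.n_years):
        veg = generate_vegetation(config, county_map, year)
        climate = generate_climate(config, year)
        spei = generate_spei(config, year)
        tables.append(compute_true_yield(veg, climate, spei, county_map, config, year))

        evi = veg["EVI"]
        lai = veg["LAI"]
        if smooth_vegetation:
            evi = replace(evi, values=sg_smooth(evi.values, axis=0))
            lai = replace(lai, values=sg_smooth(lai.values, axis=0))
        sif8 = mvc_composite(veg["SIF"], config.composite_length_days, composite_starts=starts)
        stacks = {"EVI": evi, "LAI": lai, "SIF": sif8}
        for name, st in climate.items():
            stacks[name] = aggregate_climate(st, config.composite_length_days, composite_starts=starts)

        means = {name: mask_and_average(stacks[name], county_map) for name in FEATURE_ORDER}
        for c in range(county_map.n_counties):
            values = np.column_stack([means[name][c] for name in FEATURE_ORDER])
            series.append(CountySeries(c, year, values, FEATURE_ORDER, starts))

    yields = pd.concat(tables, ignore_index=True)
    return SceneDataset(config, county_map, series, yields)
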