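"""Synthetic climate ensembles, population rasters and country HDI tables.

The generator emulates the statistical structure of the real inputs the
analysis was designed for — prescribed-SST atmospheric model ensembles of
daily maximum temperature, gridded population-density projections under
socioeconomic pathways, and country-level HDI projections — without any of
their physics. Everything is deterministic given the configuration seed.

Daily maximum temperature follows

    Tmax(cell, year, day) = baseline(lat) + seasonal(day) + dT(state)
                            + AR(1) noise(cell, year, day)

on a 365-day no-leap calendar. The AR(1) process restarts each year from its
stationary distribution, so annual index values are exchangeable across years
and decadal block maxima satisfy the extreme-value assumptions downstream.
The warmed states reuse the present state's noise realisation and differ only
by the constant offset, so warming acts as a pure shift of the daily series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    NO_COUNTRY,
    PERIODS,
    SCENARIOS,
    STATE_PRESENT,
    ConfigurationError,
    SyntheticWorldConfig,
)
from .gridio import GridSpec

DAYS_PER_YEAR = 365

# sub-stream identifiers mixed into the seed sequence so that climate,
# population and country draws are independent
_STREAM_CLIMATE = 1
_STREAM_POP = 2
_STREAM_HDI = 3


def model_grid(config: SyntheticWorldConfig) -> GridSpec:
    return GridSpec.regular_global(config.nlat, config.nlon)


def native_grid(config: SyntheticWorldConfig) -> GridSpec:
    return GridSpec.regular_global(
        config.nlat * config.native_factor, config.nlon * config.native_factor
    )


def _rng(config: SyntheticWorldConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *key]))


def noise_sd_field(config: SyntheticWorldConfig) -> np.ndarray:
    """Per-cell noise standard deviation: low inside the tropical band."""
    lat = model_grid(config).lat_centers
    lo, hi = config.low_band
    in_band = (lat >= lo) & (lat <= hi)
    sd_lat = np.where(in_band, config.sd_low, config.sd_high)
    return np.broadcast_to(sd_lat[:, None], (config.nlat, config.nlon)).copy()


def low_band_mask(config: SyntheticWorldConfig) -> np.ndarray:
    """Boolean (nlat, nlon) mask of the low-variance latitude band."""
    return noise_sd_field(config) == config.sd_low


def baseline_field(config: SyntheticWorldConfig) -> np.ndarray:
    lat = model_grid(config).lat_centers
    base = config.baseline - config.lat_gradient * np.abs(lat) / 90.0
    return np.broadcast_to(base[:, None], (config.nlat, config.nlon)).copy()


def seasonal_cycle(config: SyntheticWorldConfig) -> np.ndarray:
    """Additive seasonal cycle, shape (365,), peaking mid-year."""
    doy = np.arange(DAYS_PER_YEAR)
    return config.seasonal_amplitude * np.cos(2 * np.pi * (doy - 181) / DAYS_PER_YEAR)


def generate_climate(
    config: SyntheticWorldConfig, state: str, model: int = 0
) -> np.ndarray:
    """Daily Tmax ensemble for one climate state and synthetic model.

    Returns an array of shape ``(years, 365, nlat, nlon)`` in degrees
    Celsius. For a fixed model, all climate states share the same noise
    realisation; a warmed state is the present series plus its constant
    warming offset.
    """
    offset = config.warming_offset(state)  # validates the state label
    if not 0 <= model < config.n_models:
        raise ConfigurationError(
            f"model index {model} outside 0..{config.n_models - 1}"
        )
    shape = (config.years, config.nlat, config.nlon)
    sd = noise_sd_field(config)[None, :, :]
    phi = config.ar1
    rng = _rng(config, _STREAM_CLIMATE, model)

    noise = np.empty((config.years, DAYS_PER_YEAR, config.nlat, config.nlon))
    # stationary start each year, innovation variance sd^2 (1 - phi^2)
    noise[:, 0] = rng.standard_normal(shape) * sd
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    for d in range(1, DAYS_PER_YEAR):
        noise[:, d] = phi * noise[:, d - 1] + rng.standard_normal(shape) * innov_sd

    out = noise
    out += baseline_field(config)[None, None, :, :]
    out += seasonal_cycle(config)[None, :, None, None]
    out += offset
    return out


def generate_population(
    config: SyntheticWorldConfig, period: str, scenario: str | None = None
) -> tuple[np.ndarray, GridSpec]:
    """Population density (persons/km^2) on the native raster.

    The present field is log-normal with a fixed fraction of exactly-zero
    (uninhabited) cells; future fields keep the present spatial pattern and
    scale totals by the scenario growth factor, so uninhabited cells stay
    uninhabited across periods and pathways.
    """
    if period not in PERIODS:
        raise ConfigurationError(f"unknown period {period!r}")
    grid = native_grid(config)
    rng = _rng(config, _STREAM_POP)
    values = rng.lognormal(config.pop_log_mean, config.pop_log_sd, size=grid.shape)
    n_zero = int(round(config.pop_zero_fraction * values.size))
    flat_zero = rng.choice(values.size, size=n_zero, replace=False)
    values.flat[flat_zero] = 0.0
    if period == "future":
        if scenario not in SCENARIOS:
            raise ConfigurationError(
                f"future population needs a scenario in {SCENARIOS}, got {scenario!r}"
            )
        values = values * float(config.pop_growth[scenario])
    return values, grid


def _country_blocks(config: SyntheticWorldConfig) -> np.ndarray:
    """Partition the native raster into contiguous rectangular countries."""
    grid = native_grid(config)
    nlat, nlon = grid.shape
    n = config.n_countries
    best: tuple[int, int] | None = None
    target = nlat / nlon
    for a in range(1, n + 1):
        if n % a or a > nlat or n // a > nlon:
            continue
        b = n // a
        if best is None or abs(a / b - target) < abs(best[0] / best[1] - target):
            best = (a, b)
    if best is None:
        raise ConfigurationError(
            f"cannot tile a {nlat}x{nlon} raster with {n} rectangular countries"
        )
    a, b = best
    raster = np.empty((nlat, nlon), dtype=np.int32)
    lat_edges = np.linspace(0, nlat, a + 1).round().astype(int)
    lon_edges = np.linspace(0, nlon, b + 1).round().astype(int)
    cid = 0
    for i in range(a):
        for j in range(b):
            raster[lat_edges[i] : lat_edges[i + 1], lon_edges[j] : lon_edges[j + 1]] = cid
            cid += 1
    return raster


def generate_hdi_table(config: SyntheticWorldConfig) -> pd.DataFrame:
    """Country HDI table with present and future values per pathway.

    Present HDIs spread evenly over the configured range and are assigned to
    countries in a seed-determined shuffle. Future HDI is present HDI plus a
    pathway-dependent growth increment (rapid development > high inequality),
    capped strictly below 1, so for every country
    ``hdi_ssp1_future >= hdi_ssp4_future >= hdi_present``.
    """
    lo, hi = config.hdi_present_range
    present = np.linspace(lo, hi, config.n_countries)
    rng = _rng(config, _STREAM_HDI)
    rng.shuffle(present)
    g1 = float(config.hdi_growth["SSP1"])
    g4 = float(config.hdi_growth["SSP4"])
    if min(g1, g4) < 0:
        raise ConfigurationError("HDI growth increments must be non-negative")
    table = pd.DataFrame(
        {
            "country_id": np.arange(config.n_countries, dtype=np.int32),
            "name": [f"Country-{i:03d}" for i in range(config.n_countries)],
            "hdi_present": present,
            "hdi_ssp1_future": np.minimum(present + g1, config.hdi_cap),
            "hdi_ssp4_future": np.minimum(present + g4, config.hdi_cap),
        }
    )
    for col in ("hdi_present", "hdi_ssp1_future", "hdi_ssp4_future"):
        if not ((table[col] > 0) & (table[col] < 1)).all():
            raise ConfigurationError("generated HDI values must lie inside (0, 1)")
    return table


def generate_hdi(
    config: SyntheticWorldConfig, period: str = "present", scenario: str | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """One period/scenario HDI slice plus the native country-index raster.

    Returns ``(table, raster)`` where the table has columns ``country_id``,
    ``name`` and ``hdi``, and the raster assigns each native cell a country id
    (``NO_COUNTRY`` never occurs in the fully partitioned synthetic world but
    downstream code treats negative ids as sea).
    """
    if period not in PERIODS:
        raise ConfigurationError(f"unknown period {period!r}")
    full = generate_hdi_table(config)
    if period == "present":
        col = "hdi_present"
    else:
        if scenario not in SCENARIOS:
            raise ConfigurationError(
                f"future HDI needs a scenario in {SCENARIOS}, got {scenario!r}"
            )
        col = f"hdi_{scenario.lower()}_future"
    table = full[["country_id", "name", col]].rename(columns={col: "hdi"})
    return table, _country_blocks(config)


def country_hdi_field(
    raster: np.ndarray, table: pd.DataFrame, column: str = "hdi"
) -> np.ndarray:
    """Paint country HDI values onto a raster; sea cells become NaN."""
    lookup = pd.Series(
        table[column].to_numpy(), index=table["country_id"].to_numpy()
    )
    out = np.full(raster.shape, np.nan)
    valid = raster != NO_COUNTRY
    out[valid] = lookup.reindex(raster[valid].ravel()).to_numpy()
    return out
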