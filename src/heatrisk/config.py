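"""Configuration objects for the synthetic world and analysis runs.

The synthetic world stands in for the real inputs of the analysis: multi-model
daily-maximum-temperature ensembles under a present climate and two stabilised
warming levels, gridded population density for a present and an end-of-century
period under two socioeconomic pathways, and country-level Human Development
Index (HDI) tables. Every statistical assumption the downstream stages rely on
(10-year blocks, spatially varying interannual variability, log-normal
population, bounded HDI) is encoded here so the whole pipeline is testable
without external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: Climate-state labels. The warming offsets are relative to the present
#: state, which itself stands for the current (already warmed) decade.
STATE_PRESENT = "present"
STATE_15 = "1.5C"
STATE_2 = "2C"
CLIMATE_STATES = (STATE_PRESENT, STATE_15, STATE_2)

SCENARIOS = ("SSP1", "SSP4")
PERIODS = ("present", "future")

#: Sentinel for grid cells belonging to no country (open sea).
NO_COUNTRY = -1


class ConfigurationError(ValueError):
    """Raised when a configuration violates a structural invariant."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Address of one analysis slice: warming level x pathway x period."""

    warming: str  # one of CLIMATE_STATES
    ssp: str  # one of SCENARIOS
    period: str  # one of PERIODS

    def __post_init__(self) -> None:
        if self.warming not in CLIMATE_STATES:
            raise ConfigurationError(f"unknown warming state {self.warming!r}")
        if self.ssp not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.ssp!r}")
        if self.period not in PERIODS:
            raise ConfigurationError(f"unknown period {self.period!r}")

    @property
    def tag(self) -> str:
        return f"{self.warming}_{self.ssp}_{self.period}".replace(".", "p")


@dataclass
class SyntheticWorldConfig:
    """Parameters of the synthetic world.

    Temperature is generated as ``baseline + seasonal cycle + warming offset +
    AR(1) noise`` on a regular global latitude-longitude grid, with a 365-day
    (no-leap) calendar. The noise standard deviation is larger outside a
    contiguous low-variability latitude band, emulating the contrast between
    low interannual variability in the tropics and higher variability at
    mid-latitudes that drives the warming-to-noise amplification of extreme
    heatwave frequencies.

    Population and countries live on a finer "native" raster
    (``native_factor`` times the model resolution in each direction) and are
    remapped onto the model grid by the pipeline, mirroring how observational
    population products are regridded onto each climate model grid.
    """

    # model grid
    nlat: int = 8
    nlon: int = 8
    # synthetic multi-model ensemble
    n_models: int = 2
    years: int = 500  # per climate state, per model
    # climate
    baseline: float = 25.0  # degC, annual-mean Tmax at the equator
    lat_gradient: float = 10.0  # degC drop from equator to pole
    seasonal_amplitude: float = 8.0  # degC, half peak-to-trough
    ar1: float = 0.7  # day-to-day autocorrelation, reset every year
    sd_low: float = 1.0  # degC, noise sd in the low-variance band
    sd_high: float = 3.0  # degC, noise sd elsewhere
    low_band: tuple[float, float] = (-20.0, 20.0)  # deg latitude
    dt_15: float = 0.6  # degC above present at the 1.5 degC level
    dt_2: float = 1.1  # degC above present at the 2 degC level
    # population (native raster)
    native_factor: int = 2
    pop_log_mean: float = 4.0  # log persons/km^2
    pop_log_sd: float = 1.2
    pop_zero_fraction: float = 0.2  # uninhabited cells
    pop_growth: Mapping[str, float] = field(
        default_factory=lambda: {"SSP1": 1.2, "SSP4": 1.4}
    )
    # countries / HDI
    n_countries: int = 32
    hdi_present_range: tuple[float, float] = (0.35, 0.93)
    hdi_growth: Mapping[str, float] = field(
        default_factory=lambda: {"SSP1": 0.08, "SSP4": 0.03}
    )
    hdi_cap: float = 0.98  # future HDI stays strictly below 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.years < 200 or self.years % 10 != 0:
            raise ConfigurationError(
                "ensemble years must be >= 200 and divisible by the 10-year "
                f"block length, got {self.years}"
            )
        if not (self.dt_2 > self.dt_15 > 0):
            raise ConfigurationError(
                "warming offsets must satisfy dt_2 > dt_15 > 0, got "
                f"dt_15={self.dt_15}, dt_2={self.dt_2}"
            )
        if not 0 <= self.pop_zero_fraction <= 1:
            raise ConfigurationError("pop_zero_fraction must be in [0, 1]")
        for ssp, g in self.pop_growth.items():
            if g < 0:
                raise ConfigurationError(f"negative growth factor for {ssp}: {g}")
        lo, hi = self.hdi_present_range
        if not (0 < lo < hi < 1):
            raise ConfigurationError("hdi_present_range must lie inside (0, 1)")
        if not 0 < self.hdi_cap < 1:
            raise ConfigurationError("hdi_cap must lie inside (0, 1)")
        if self.n_countries < 3:
            raise ConfigurationError("need >= 3 countries to populate HDI classes")
        if self.nlat < 2 or self.nlon < 2:
            raise ConfigurationError("grid must be at least 2x2")
        if not 0 <= self.ar1 < 1:
            raise ConfigurationError("AR(1) coefficient must be in [0, 1)")

    def warming_offset(self, state: str) -> float:
        if state == STATE_PRESENT:
            return 0.0
        if state == STATE_15:
            return self.dt_15
        if state == STATE_2:
            return self.dt_2
        raise ConfigurationError(f"unknown climate state {state!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pop_growth"] = dict(self.pop_growth)
        d["hdi_growth"] = dict(self.hdi_growth)
        d["low_band"] = list(self.low_band)
        d["hdi_present_range"] = list(self.hdi_present_range)
        return d


@dataclass
class RunConfig:
    """Full pipeline configuration: world + analysis settings."""

    world: SyntheticWorldConfig = field(default_factory=SyntheticWorldConfig)
    block_length: int = 10  # years per block of the extreme-value analysis
    return_period: int = 500  # blocks (decades); 100 gives the HW100Y variant
    min_blocks: int = 20
    ad_bootstrap: int = 200
    ks_alpha: float = 0.05
    # reading grids for the population tables
    hazard_bins: tuple[float, ...] = (0.0, 0.002, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)
    iri_bins: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)

    def to_dict(self) -> dict:
        return {
            "world": self.world.to_dict(),
            "block_length": self.block_length,
            "return_period": self.return_period,
            "min_blocks": self.min_blocks,
            "ad_bootstrap": self.ad_bootstrap,
            "ks_alpha": self.ks_alpha,
            "hazard_bins": list(self.hazard_bins),
            "iri_bins": list(self.iri_bins),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        world = d.pop("world", {})
        if isinstance(world, Mapping):
            world = dict(world)
            for key in ("low_band", "hdi_present_range"):
                if key in world:
                    world[key] = tuple(world[key])
            world = SyntheticWorldConfig(**world)
        cfg = cls(world=world)
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise ConfigurationError(f"unknown run-config key {key!r}")
            if key in ("hazard_bins", "iri_bins"):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
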