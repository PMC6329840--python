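"""End-to-end orchestration: synthetic world -> hazard -> normalization -> IRI.

The pipeline mirrors the study design: for each synthetic climate model it
computes annual HWMId (and TX5x) series for the present and the 1.5/2 degC
states, fits GEV distributions to decadal block maxima, evaluates the
probability of exceeding the present extreme-heatwave return level under each
warmed state, normalizes population and (1 - HDI) through present-period
Johnson fits, combines the three factors into normalized and non-normalized
IRI fields for every warming x pathway combination, and aggregates population
into hazard- and IRI-bin tables with ensemble medians and ranges plus the
scenario-difference fields.

Because the synthetic world is fully determined by its seed, stages always
regenerate their climate inputs in memory rather than reading the (large)
daily NetCDF files back; ``simulate`` exists to materialise the synthetic
inputs for external use.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .config import (
    SCENARIOS,
    STATE_15,
    STATE_2,
    STATE_PRESENT,
    CLIMATE_STATES,
    RunConfig,
)
from . import gev, indices, johnson, risk, synthetic
from .gridio import (
    GridSpec,
    field_to_dataarray,
    rasterize_countries,
    remap_conservative,
    write_dataset,
    write_table,
)

WARMING_STATES = (STATE_15, STATE_2)

#: The headline scenario-difference fields (normalized IRI, future period).
DIFFERENCE_KEYS = (
    ("warming_SSP1", (STATE_2, "SSP1"), (STATE_15, "SSP1")),
    ("warming_SSP4", (STATE_2, "SSP4"), (STATE_15, "SSP4")),
    ("ssp_1p5C", (STATE_15, "SSP4"), (STATE_15, "SSP1")),
    ("ssp_2C", (STATE_2, "SSP4"), (STATE_2, "SSP1")),
    ("worst_minus_best", (STATE_2, "SSP4"), (STATE_15, "SSP1")),
)


@dataclass
class ModelHazard:
    """Hazard stage outputs for one synthetic climate model."""

    model: int
    thresholds: indices.ThresholdClimatology
    quartiles: indices.ReferenceQuartiles
    hwmid: dict[str, np.ndarray]  # state -> (years, nlat, nlon)
    tx5x: dict[str, np.ndarray]
    gev_params: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    level: np.ndarray  # present-climate T-block return level
    hazard_p: dict[str, np.ndarray]  # state -> per-decade exceedance prob
    ad_pvalue: dict[str, np.ndarray]


@dataclass
class WorldData:
    """Socioeconomic stage outputs shared by all models (one model grid)."""

    grid: GridSpec
    native: GridSpec
    pop_native: dict[tuple[str, str | None], np.ndarray]
    pop_model: dict[tuple[str, str | None], np.ndarray]
    country_native: np.ndarray
    country_model: np.ndarray
    hdi_table: pd.DataFrame
    hdi_fields: dict[tuple[str, str | None], np.ndarray]  # painted on model grid
    pop_fit: johnson.JohnsonFit
    vuln_fit: johnson.JohnsonFit
    pop_scores: dict[tuple[str, str | None], np.ndarray]
    vuln_scores: dict[tuple[str, str | None], np.ndarray]
    classes: np.ndarray
    present_people: float


@dataclass
class RunResult:
    config: RunConfig
    world: WorldData
    models: list[ModelHazard]
    iri_norm: dict[tuple[int, str, str], np.ndarray] = field(default_factory=dict)
    iri_nonnorm: dict[tuple[int, str, str], np.ndarray] = field(default_factory=dict)
    iri_present: dict[int, np.ndarray] = field(default_factory=dict)
    differences: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    exposure_hazard: pd.DataFrame | None = None
    exposure_iri: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stage computations
# ---------------------------------------------------------------------------


def compute_model_hazard(cfg: RunConfig, model: int) -> ModelHazard:
    """Indices + extreme-value stage for one synthetic model.

    Thresholds and reference quartiles come from the model's own present-state
    run (the baseline climate); the same climatology scales all states so a
    warmed series yields larger magnitudes.
    """
    w = cfg.world
    present = synthetic.generate_climate(w, STATE_PRESENT, model)
    thresholds = indices.compute_thresholds(present)
    quartiles = indices.reference_quartiles(present)

    hwmid: dict[str, np.ndarray] = {}
    tx5x: dict[str, np.ndarray] = {}
    gev_params: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    ad_pvalue: dict[str, np.ndarray] = {}
    for si, state in enumerate(CLIMATE_STATES):
        # warmed states are the present run plus a constant offset
        daily = present if state == STATE_PRESENT else present + w.warming_offset(state)
        hwmid[state] = indices.hwmid_series(daily, thresholds, quartiles)
        tx5x[state] = indices.tx5x_series(daily)
        bm = gev.block_maxima(hwmid[state], cfg.block_length)
        flat = bm.reshape(bm.shape[0], -1).T  # (ncell, nblocks)
        gev_params[state] = tuple(
            p.reshape(w.nlat, w.nlon) for p in gev.fit_gev_lmoments_batch(flat)
        )
        pvals = np.full(flat.shape[0], np.nan)
        for c in range(flat.shape[0]):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(w.seed), 4, model, si, c])
            )
            _, pvals[c] = gev.ad_test_gev(
                flat[c], n_boot=cfg.ad_bootstrap, rng=rng, min_blocks=cfg.min_blocks
            )
        ad_pvalue[state] = pvals.reshape(w.nlat, w.nlon)

    level = np.asarray(gev.return_level(gev_params[STATE_PRESENT], cfg.return_period))
    hazard_p = {
        state: np.asarray(gev.exceedance_probability(gev_params[state], level))
        for state in CLIMATE_STATES
    }
    return ModelHazard(
        model=model,
        thresholds=thresholds,
        quartiles=quartiles,
        hwmid=hwmid,
        tx5x=tx5x,
        gev_params=gev_params,
        level=level,
        hazard_p=hazard_p,
        ad_pvalue=ad_pvalue,
    )


def _slices() -> list[tuple[str, str | None]]:
    return [("present", None)] + [("future", ssp) for ssp in SCENARIOS]


def compute_world(cfg: RunConfig) -> WorldData:
    """Population, countries, HDI, remapping and Johnson normalization."""
    w = cfg.world
    grid = synthetic.model_grid(w)
    native = synthetic.native_grid(w)

    pop_native = {}
    pop_model = {}
    for period, ssp in _slices():
        values, _ = synthetic.generate_population(w, period, ssp)
        pop_native[(period, ssp)] = values
        pop_model[(period, ssp)] = remap_conservative(values, native, grid)

    hdi_table = synthetic.generate_hdi_table(w)
    country_native = synthetic._country_blocks(w)
    country_model = rasterize_countries(country_native, native, grid)

    hdi_fields = {}
    for period, ssp in _slices():
        col = "hdi_present" if period == "present" else f"hdi_{ssp.lower()}_future"
        hdi_fields[(period, ssp)] = synthetic.country_hdi_field(
            country_model, hdi_table, col
        )

    pop_fit = johnson.fit_johnson(
        pop_model[("present", None)], johnson.SUPPORT_NONNEGATIVE
    )
    vuln_present = 1.0 - hdi_fields[("present", None)]
    vuln_fit = johnson.fit_johnson(vuln_present, johnson.SUPPORT_UNIT_INTERVAL)

    pop_scores = {
        key: johnson.normalize_field(val, pop_fit) for key, val in pop_model.items()
    }
    vuln_scores = {
        key: johnson.normalize_field(1.0 - val, vuln_fit)
        for key, val in hdi_fields.items()
    }
    classes = risk.classify_hdi(hdi_fields[("present", None)])
    present_people = float(
        risk.people_per_cell(pop_model[("present", None)], grid).sum()
    )
    return WorldData(
        grid=grid,
        native=native,
        pop_native=pop_native,
        pop_model=pop_model,
        country_native=country_native,
        country_model=country_model,
        hdi_table=hdi_table,
        hdi_fields=hdi_fields,
        pop_fit=pop_fit,
        vuln_fit=vuln_fit,
        pop_scores=pop_scores,
        vuln_scores=vuln_scores,
        classes=classes,
        present_people=present_people,
    )


def compute_iri(result: RunResult) -> None:
    """Fill the normalized/non-normalized IRI fields and difference maps."""
    world = result.world
    for mh in result.models:
        m = mh.model
        result.iri_present[m] = risk.iri_normalized(
            mh.hazard_p[STATE_PRESENT],
            world.pop_scores[("present", None)],
            world.vuln_scores[("present", None)],
        )
        for warming in WARMING_STATES:
            for ssp in SCENARIOS:
                key = (m, warming, ssp)
                result.iri_norm[key] = risk.iri_normalized(
                    mh.hazard_p[warming],
                    world.pop_scores[("future", ssp)],
                    world.vuln_scores[("future", ssp)],
                )
                result.iri_nonnorm[key] = risk.iri_nonnormalized(
                    mh.hazard_p[warming],
                    world.pop_model[("future", ssp)],
                    1.0 - world.hdi_fields[("future", ssp)],
                )
        for name, (wa, sa), (wb, sb) in DIFFERENCE_KEYS:
            result.differences[(m, name)] = risk.scenario_difference(
                result.iri_norm[(m, wa, sa)], result.iri_norm[(m, wb, sb)]
            )


_SCOPES = {
    "global": None,
    "low_hdi": risk.HDIClass.LOW,
    "medium_hdi": risk.HDIClass.MEDIUM,
    "very_high_hdi": risk.HDIClass.VERY_HIGH,
}


def compute_exposure_tables(result: RunResult) -> None:
    """Population-by-bin tables for hazard probability and normalized IRI."""
    cfg, world = result.config, result.world
    rows_hazard: list[pd.DataFrame] = []
    rows_iri: list[pd.DataFrame] = []
    for scope_name, scope_class in _SCOPES.items():
        mask = risk.class_mask(world.classes, scope_class)
        for warming in WARMING_STATES:
            for ssp in SCENARIOS:
                pop = world.pop_model[("future", ssp)]
                per_model_h = []
                per_model_i = []
                for mh in result.models:
                    per_model_h.append(
                        risk.exposure_distribution(
                            mh.hazard_p[warming], pop, world.grid,
                            np.asarray(cfg.hazard_bins), world.present_people, mask,
                        )
                    )
                    per_model_i.append(
                        risk.exposure_distribution(
                            result.iri_norm[(mh.model, warming, ssp)], pop,
                            world.grid, np.asarray(cfg.iri_bins),
                            world.present_people, mask,
                        )
                    )
                for rows, tables in ((rows_hazard, per_model_h), (rows_iri, per_model_i)):
                    summary = risk.ensemble_summary(tables)
                    summary.insert(0, "scope", scope_name)
                    summary.insert(1, "scenario", ssp)
                    summary.insert(2, "warming", warming)
                    rows.append(summary)
    result.exposure_hazard = pd.concat(rows_hazard, ignore_index=True)
    result.exposure_iri = pd.concat(rows_iri, ignore_index=True)


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------


def _grid_da(arr, grid, name, units=None, **extra):
    return field_to_dataarray(arr, grid, name, units=units, extra_dims=extra or None)


def write_artifacts(result: RunResult, outdir: Path) -> list[str]:
    """Write the derived NetCDF/CSV/JSON bundle; returns relative paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg, world = result.config, result.world
    written: list[str] = []

    def _w(obj, rel, writer):
        writer(obj, outdir / rel)
        written.append(rel)

    # socioeconomic inputs and scores
    full = world.hdi_table
    _w(full, "hdi_countries.csv", write_table)
    _w(
        _grid_da(world.country_model, world.grid, "country_index"),
        "country_index_model.nc", write_dataset,
    )
    for (period, ssp), pop in world.pop_model.items():
        tag = period if ssp is None else f"{period}_{ssp}"
        ds = xr.Dataset(
            {
                f"pop_density": _grid_da(pop, world.grid, "pop_density", "persons km-2"),
                f"pop_norm": _grid_da(world.pop_scores[(period, ssp)], world.grid, "pop_norm", "1"),
                f"vuln_norm": _grid_da(world.vuln_scores[(period, ssp)], world.grid, "vuln_norm", "1"),
                f"hdi": _grid_da(world.hdi_fields[(period, ssp)], world.grid, "hdi", "1"),
            }
        )
        _w(ds, f"society_{tag}.nc", write_dataset)
    fits = {
        "population": vars(world.pop_fit).copy(),
        "vulnerability": vars(world.vuln_fit).copy(),
    }
    (outdir / "johnson_fits.json").write_text(json.dumps(fits, indent=2))
    written.append("johnson_fits.json")

    years = np.arange(cfg.world.years)
    for mh in result.models:
        ds = xr.Dataset(
            {"thresholds": _grid_da(mh.thresholds.thresholds, world.grid, "thresholds", "degC", dayofyear=np.arange(1, 366))}
        )
        _w(ds, f"thresholds_model{mh.model}.nc", write_dataset)
        for state in CLIMATE_STATES:
            tag = f"model{mh.model}_{state}".replace(".", "p")
            ds = xr.Dataset(
                {
                    "hwmid": _grid_da(mh.hwmid[state], world.grid, "hwmid", "1", year=years),
                    "tx5x": _grid_da(mh.tx5x[state], world.grid, "tx5x", "degC", year=years),
                }
            )
            _w(ds, f"indices_{tag}.nc", write_dataset)
        hazard_vars = {
            "hw500y_level": _grid_da(mh.level, world.grid, "hw500y_level", "1"),
        }
        for state in CLIMATE_STATES:
            s = state.replace(".", "p")
            mu, sigma, xi = mh.gev_params[state]
            hazard_vars[f"gev_location_{s}"] = _grid_da(mu, world.grid, "gev_location")
            hazard_vars[f"gev_scale_{s}"] = _grid_da(sigma, world.grid, "gev_scale")
            hazard_vars[f"gev_shape_{s}"] = _grid_da(xi, world.grid, "gev_shape")
            hazard_vars[f"hazard_probability_{s}"] = _grid_da(
                mh.hazard_p[state], world.grid, "hazard_probability", "1"
            )
            hazard_vars[f"ad_pvalue_{s}"] = _grid_da(
                mh.ad_pvalue[state], world.grid, "ad_pvalue", "1"
            )
        _w(xr.Dataset(hazard_vars), f"hazard_model{mh.model}.nc", write_dataset)

        iri_vars = {
            "iri_norm_present": _grid_da(result.iri_present[mh.model], world.grid, "iri", "percent")
        }
        for warming in WARMING_STATES:
            for ssp in SCENARIOS:
                s = warming.replace(".", "p")
                iri_vars[f"iri_norm_{s}_{ssp}"] = _grid_da(
                    result.iri_norm[(mh.model, warming, ssp)], world.grid, "iri", "percent"
                )
                iri_vars[f"iri_nonnorm_{s}_{ssp}"] = _grid_da(
                    result.iri_nonnorm[(mh.model, warming, ssp)], world.grid,
                    "iri_nonnorm", "persons km-2",
                )
        for name, _, _ in DIFFERENCE_KEYS:
            iri_vars[f"iri_diff_{name}"] = _grid_da(
                result.differences[(mh.model, name)], world.grid, "iri_diff", "percent"
            )
        _w(xr.Dataset(iri_vars), f"iri_model{mh.model}.nc", write_dataset)

    _w(result.exposure_hazard, "exposure_hazard.csv", write_table)
    _w(result.exposure_iri, "exposure_iri.csv", write_table)
    return written


def run_all(
    cfg: RunConfig, outdir: str | Path | None = None, save_climate: bool = False
) -> RunResult:
    """Execute the full pipeline; write the artifact bundle if outdir given."""
    t0 = time.time()
    stages: dict[str, float] = {}
    world = compute_world(cfg)
    stages["world"] = time.time() - t0

    models = []
    for m in range(cfg.world.n_models):
        tm = time.time()
        models.append(compute_model_hazard(cfg, m))
        stages[f"hazard_model{m}"] = time.time() - tm

    result = RunResult(config=cfg, world=world, models=models)
    tm = time.time()
    compute_iri(result)
    compute_exposure_tables(result)
    stages["iri_exposure"] = time.time() - tm

    result.manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.world.seed,
        "stage_seconds": {k: round(v, 3) for k, v in stages.items()},
        "artifacts": [],
    }
    if outdir is not None:
        outdir = Path(outdir)
        written = write_artifacts(result, outdir)
        if save_climate:
            written += write_climate(cfg, outdir)
        result.manifest["artifacts"] = written
        (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    return result


def write_climate(cfg: RunConfig, outdir: Path) -> list[str]:
    """Materialise the raw synthetic daily-Tmax ensembles as NetCDF."""
    outdir = Path(outdir)
    written = []
    w = cfg.world
    grid = synthetic.model_grid(w)
    for m in range(w.n_models):
        for state in CLIMATE_STATES:
            daily = synthetic.generate_climate(w, state, m)
            flat = daily.reshape(-1, w.nlat, w.nlon)
            da = field_to_dataarray(
                flat, grid, "tasmax", units="degC",
                extra_dims={"time": np.arange(flat.shape[0])},
            )
            da.attrs["calendar"] = "365_day"
            rel = f"tasmax_model{m}_{state.replace('.', 'p')}.nc"
            write_dataset(da, outdir / rel)
            written.append(rel)
    return written
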