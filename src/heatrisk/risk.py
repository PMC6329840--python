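"""Illustrative Risk Index (IRI), HDI classes and population-exposure tables.

The normalized IRI at a grid cell is

    IRI = hazard * exposure * vulnerability * 100      (percent)

with all three factors in [0, 1]: the per-decade probability of exceeding the
present-climate extreme-heatwave return level, the Johnson-normalized
population density, and the Johnson-normalized (1 - HDI). The non-normalized
variant multiplies the hazard probability by raw population density
(persons/km^2) and raw (1 - HDI) and keeps physical units.

Countries are grouped by the fixed Human Development Report cutoffs:
low development HDI < 0.55, very high development HDI > 0.8 (strict
inequalities; everything between is the medium band).

Exposure tables distribute people — cell density times spherical cell area,
restricted to inhabited cells — over hazard-probability or IRI bins and
report each bin as a percentage of the present global population.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np
import pandas as pd

from .gridio import GridSpec

HDI_LOW_CUTOFF = 0.55
HDI_VERY_HIGH_CUTOFF = 0.8


class HDIClass(IntEnum):
    NO_DATA = -1
    LOW = 0
    MEDIUM = 1
    VERY_HIGH = 2


def iri_normalized(hazard, pop_score, vuln_score) -> np.ndarray:
    """Normalized IRI in percent; every factor must lie in [0, 1]."""
    arrays = [np.asarray(a, dtype=float) for a in (hazard, pop_score, vuln_score)]
    for name, a in zip(("hazard", "pop_score", "vuln_score"), arrays):
        finite = a[np.isfinite(a)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError(f"{name} has values outside [0, 1]")
    return arrays[0] * arrays[1] * arrays[2] * 100.0


def iri_nonnormalized(hazard, pop_density, one_minus_hdi) -> np.ndarray:
    """Raw-product risk index: probability x persons/km^2 x (1 - HDI)."""
    hazard = np.asarray(hazard, dtype=float)
    pop = np.asarray(pop_density, dtype=float)
    vuln = np.asarray(one_minus_hdi, dtype=float)
    finite = pop[np.isfinite(pop)]
    if finite.size and finite.min() < 0:
        raise ValueError("population density must be non-negative")
    return hazard * pop * vuln


def classify_hdi(hdi_field: np.ndarray) -> np.ndarray:
    """Per-cell development class from a (country-painted) HDI field."""
    hdi = np.asarray(hdi_field, dtype=float)
    out = np.full(hdi.shape, int(HDIClass.MEDIUM), dtype=np.int8)
    out[hdi < HDI_LOW_CUTOFF] = int(HDIClass.LOW)
    out[hdi > HDI_VERY_HIGH_CUTOFF] = int(HDIClass.VERY_HIGH)
    out[~np.isfinite(hdi)] = int(HDIClass.NO_DATA)
    return out


def class_mask(classes: np.ndarray, which: HDIClass | None) -> np.ndarray:
    """Boolean mask for one development class (None = all classes with data)."""
    classes = np.asarray(classes)
    if which is None:
        return classes != int(HDIClass.NO_DATA)
    return classes == int(which)


def people_per_cell(pop_density: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Persons per cell: density (per km^2) times spherical cell area."""
    pop = np.asarray(pop_density, dtype=float)
    if pop.shape != grid.shape:
        raise ValueError(f"population shape {pop.shape} != grid {grid.shape}")
    return pop * grid.cell_areas_km2()


def exposure_distribution(
    field: np.ndarray,
    pop_density: np.ndarray,
    grid: GridSpec,
    bin_edges: np.ndarray,
    present_global_people: float,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Population share (percent of present global population) per field bin.

    Only cells with population density > 0 (and inside ``mask``, if given)
    contribute. ``bin_edges`` must be strictly increasing; the last bin is
    closed on the right, as in ``numpy.histogram``.
    """
    field = np.asarray(field, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing (non-overlapping bins)")
    if present_global_people <= 0:
        raise ValueError("present global population must be positive")
    people = people_per_cell(pop_density, grid)
    keep = (np.asarray(pop_density, dtype=float) > 0) & np.isfinite(field)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    counts, _ = np.histogram(field[keep], bins=edges, weights=people[keep])
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "pop_pct": counts / present_global_people * 100.0,
        }
    )


def ensemble_summary(tables: list[pd.DataFrame], value_col: str = "pop_pct") -> pd.DataFrame:
    """Per-bin median/min/max across the model ensemble."""
    if not tables:
        raise ValueError("need at least one table")
    base = tables[0][["bin_low", "bin_high"]]
    for t in tables[1:]:
        if not np.array_equal(t["bin_low"], base["bin_low"]) or not np.array_equal(
            t["bin_high"], base["bin_high"]
        ):
            raise ValueError("ensemble tables must share identical bins")
    stack = np.stack([t[value_col].to_numpy() for t in tables])
    out = base.copy()
    out["pop_pct_median"] = np.median(stack, axis=0)
    out["pop_pct_min"] = stack.min(axis=0)
    out["pop_pct_max"] = stack.max(axis=0)
    return out


def scenario_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cell-wise difference of two same-variant risk fields (NaN propagates)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"field shapes differ: {a.shape} vs {b.shape}")
    return a - b
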