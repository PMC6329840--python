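"""Grid handling, conservative remapping and NetCDF/CSV artifact I/O.

Regular latitude-longitude grids only. Remapping is first-order conservative:
each target cell takes the area-overlap-weighted mean of the source cells it
intersects, so the area integral of a density field (for instance persons/km^2)
is preserved exactly up to rounding. Longitudes use the [-180, 180) convention
with half-open cells; latitudes run from south to north.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0


class RemapError(ValueError):
    """Raised when two grids cannot be conservatively remapped."""


@dataclass(frozen=True)
class GridSpec:
    """A regular latitude-longitude grid: cell centres and bounds.

    ``lat_bounds``/``lon_bounds`` have one more element than the centres and
    tile the domain without overlap.
    """

    lat_centers: np.ndarray
    lat_bounds: np.ndarray
    lon_centers: np.ndarray
    lon_bounds: np.ndarray

    def __post_init__(self) -> None:
        for b in (self.lat_bounds, self.lon_bounds):
            if np.any(np.diff(b) <= 0):
                raise RemapError("grid bounds must be strictly increasing")
        if len(self.lat_bounds) != len(self.lat_centers) + 1:
            raise RemapError("lat bounds must have one more element than centres")
        if len(self.lon_bounds) != len(self.lon_centers) + 1:
            raise RemapError("lon bounds must have one more element than centres")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lat_centers), len(self.lon_centers))

    @classmethod
    def regular_global(cls, nlat: int, nlon: int) -> "GridSpec":
        lat_b = np.linspace(-90.0, 90.0, nlat + 1)
        lon_b = np.linspace(-180.0, 180.0, nlon + 1)
        return cls(
            lat_centers=0.5 * (lat_b[:-1] + lat_b[1:]),
            lat_bounds=lat_b,
            lon_centers=0.5 * (lon_b[:-1] + lon_b[1:]),
            lon_bounds=lon_b,
        )

    def cell_areas_km2(self) -> np.ndarray:
        """Spherical cell areas, shape (nlat, nlon)."""
        sin_lat = np.sin(np.deg2rad(self.lat_bounds))
        band = EARTH_RADIUS_KM**2 * np.diff(sin_lat)  # per radian of longitude
        dlon = np.deg2rad(np.diff(self.lon_bounds))
        return np.outer(band, dlon)


def _interval_overlap(dst_bounds: np.ndarray, src_bounds: np.ndarray) -> np.ndarray:
    """Pairwise overlap lengths between destination and source intervals."""
    lo = np.maximum(dst_bounds[:-1, None], src_bounds[None, :-1])
    hi = np.minimum(dst_bounds[1:, None], src_bounds[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def overlap_matrices(src: GridSpec, dst: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Area-overlap weight matrices along latitude and longitude.

    Latitude overlaps are measured in sin(latitude) so that the product of the
    two matrices gives true spherical area overlaps (up to the constant
    R^2 factor, which cancels in means).
    """
    w_lat = _interval_overlap(
        np.sin(np.deg2rad(dst.lat_bounds)), np.sin(np.deg2rad(src.lat_bounds))
    )
    w_lon = _interval_overlap(np.deg2rad(dst.lon_bounds), np.deg2rad(src.lon_bounds))
    if w_lat.sum() == 0 or w_lon.sum() == 0:
        raise RemapError("source and target grids do not overlap")
    return w_lat, w_lon


def remap_conservative(
    field: np.ndarray, src: GridSpec, dst: GridSpec
) -> np.ndarray:
    """First-order conservative remap of an intensive (density) field.

    The target value is the overlap-area-weighted mean of the source values,
    so the global area integral of the field is conserved. NaNs are treated
    as zero density.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != src.shape:
        raise RemapError(f"field shape {field.shape} != source grid {src.shape}")
    w_lat, w_lon = overlap_matrices(src, dst)
    f = np.where(np.isfinite(field), field, 0.0)
    integral = w_lat @ f @ w_lon.T
    dst_area = np.outer(
        np.diff(np.sin(np.deg2rad(dst.lat_bounds))), np.diff(np.deg2rad(dst.lon_bounds))
    )
    return integral / dst_area


def rasterize_countries(
    raster: np.ndarray, src: GridSpec, dst: GridSpec
) -> np.ndarray:
    """Remap an integer country-index raster by the majority-area rule.

    Ties are broken towards the lowest country id. Cells whose dominant
    contribution is the sentinel (negative id) stay sentinel.
    """
    raster = np.asarray(raster)
    if raster.shape != src.shape:
        raise RemapError(f"raster shape {raster.shape} != source grid {src.shape}")
    w_lat, w_lon = overlap_matrices(src, dst)
    ids = np.unique(raster)
    fractions = np.empty((len(ids),) + dst.shape)
    for k, cid in enumerate(ids):
        fractions[k] = w_lat @ (raster == cid).astype(float) @ w_lon.T
    # argmax returns the first maximum; ids are sorted ascending, so ties
    # resolve to the lowest id.
    best = np.argmax(fractions, axis=0)
    return ids[best]


# ---------------------------------------------------------------------------
# NetCDF / CSV artifacts
# ---------------------------------------------------------------------------


def field_to_dataarray(
    field: np.ndarray,
    grid: GridSpec,
    name: str,
    units: str | None = None,
    extra_dims: dict[str, np.ndarray] | None = None,
) -> xr.DataArray:
    """Wrap a (…, lat, lon) array as a CF-flavoured DataArray."""
    dims: list[str] = []
    coords: dict[str, np.ndarray] = {}
    if extra_dims:
        for dim, values in extra_dims.items():
            dims.append(dim)
            coords[dim] = np.asarray(values)
    dims += ["lat", "lon"]
    coords["lat"] = grid.lat_centers
    coords["lon"] = grid.lon_centers
    da = xr.DataArray(np.asarray(field), dims=dims, coords=coords, name=name)
    da["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    da["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    if units is not None:
        da.attrs["units"] = units
    return da


def write_dataset(ds: xr.Dataset | xr.DataArray, path: str | Path) -> Path:
    """Write a dataset as classic NetCDF with NaN declared as _FillValue."""
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    encoding = {}
    for name, var in ds.data_vars.items():
        if np.issubdtype(var.dtype, np.floating):
            encoding[name] = {"_FillValue": np.nan}
    ds.to_netcdf(path, engine="scipy", encoding=encoding)
    return path


def read_dataset(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
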