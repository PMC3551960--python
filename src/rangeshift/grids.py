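"""Grid data model and geographic I/O.

Everything in the pipeline lives on a regular latitude-longitude grid with
cell-center coordinates, latitude ascending and longitude in [-180, 180).
Missing (land) cells are NaN. One kilometres-per-degree constant,
:data:`KM_PER_DEGREE`, is used for every degree-to-km conversion in the
package so that centroid shifts and cell areas are mutually consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

#: Kilometres per degree of latitude on a spherical mean Earth.
KM_PER_DEGREE = 111.32

#: Environmental variables the pipeline knows about.
KNOWN_VARIABLES = ("sst", "sbt", "salinity", "ice", "npp", "depth", "dist_coast")

_NETCDF_ENGINE = "scipy"


class GridError(ValueError):
    """Raised for malformed grids, disjoint domains or unreadable layers."""


@dataclass(frozen=True)
class GridSpec:
    """A regular lat-lon grid defined by its outer edges and resolution.

    Cell centers sit at ``edge + resolution/2``; the number of rows/columns
    must divide the extent exactly.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.5

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise GridError("resolution must be positive")
        for lo, hi, axis in ((self.lat_min, self.lat_max, "lat"), (self.lon_min, self.lon_max, "lon")):
            n = (hi - lo) / self.resolution
            if hi <= lo or abs(n - round(n)) > 1e-9:
                raise GridError(f"{axis} extent [{lo}, {hi}] is not a whole number of {self.resolution} deg cells")

    @property
    def n_lat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def n_lon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.resolution * (np.arange(self.n_lat) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.resolution * (np.arange(self.n_lon) + 0.5)

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the half-open cell [edge, edge+res) containing a point."""
        i = int(np.floor((lat - self.lat_min) / self.resolution))
        j = int(np.floor((lon - self.lon_min) / self.resolution))
        if not (0 <= i < self.n_lat and 0 <= j < self.n_lon):
            raise GridError(f"point ({lon}, {lat}) outside grid bounds")
        return i, j

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lat >= self.lat_min)
            & (lat < self.lat_max)
            & (lon >= self.lon_min)
            & (lon < self.lon_max)
        )


def _check_shape(spec: GridSpec, values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != spec.shape:
        raise GridError(f"{what} shape {values.shape} does not match grid {spec.shape}")
    return values


@dataclass
class EnvGrid:
    """One environmental layer (2-D field, NaN = missing/land) on a GridSpec."""

    spec: GridSpec
    variable: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = _check_shape(self.spec, self.values, f"layer '{self.variable}'")
        if self.variable == "depth" and np.nanmin(self.values, initial=0.0) < 0:
            raise GridError("depth must be >= 0 where present")
        if self.variable == "ice":
            v = self.values[np.isfinite(self.values)]
            if v.size and (v.min() < 0 or v.max() > 1):
                raise GridError("ice concentration must lie in [0, 1]")

    @property
    def sea_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class EnvStack:
    """All environmental layers for one averaged period, on one shared grid."""

    period_label: str
    layers: dict[str, EnvGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        specs = {id(g.spec): g.spec for g in self.layers.values()}
        if len({(s.lat_min, s.lat_max, s.lon_min, s.lon_max, s.resolution) for s in specs.values()}) > 1:
            raise GridError("all layers in a stack must share one GridSpec")

    @property
    def spec(self) -> GridSpec:
        if not self.layers:
            raise GridError("empty stack")
        return next(iter(self.layers.values())).spec

    def __getitem__(self, variable: str) -> EnvGrid:
        try:
            return self.layers[variable]
        except KeyError:
            raise GridError(f"stack '{self.period_label}' has no layer '{variable}'") from None

    def require(self, variables) -> None:
        missing = [v for v in variables if v not in self.layers]
        if missing:
            raise GridError(f"stack '{self.period_label}' missing layers: {missing}")

    @property
    def sea_mask(self) -> np.ndarray:
        """Cells finite in every layer."""
        mask = np.ones(self.spec.shape, dtype=bool)
        for g in self.layers.values():
            mask &= g.sea_mask
        return mask


@dataclass
class RegionMask:
    """Boolean membership grid for a named basin/region."""

    spec: GridSpec
    member: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.spec.shape:
            raise GridError("region mask shape does not match grid")


@dataclass
class SuitabilityMap:
    """Per-cell relative habitat suitability in [0, 1] (NaN = missing)."""

    spec: GridSpec
    values: np.ndarray
    species: str = ""
    model: str = ""
    period: str = ""

    def __post_init__(self) -> None:
        self.values = _check_shape(self.spec, self.values, "suitability")
        v = self.values[np.isfinite(self.values)]
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise GridError("suitability values must lie in [0, 1]")

    def with_values(self, values: np.ndarray) -> "SuitabilityMap":
        return replace(self, values=np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# geometry helpers

def cell_area_km2(lat_center, resolution: float):
    """Area of a resolution x resolution cell centred at ``lat_center``.

    Treats the cell as (K*res) km tall and (K*res*cos(lat)) km wide with
    K = :data:`KM_PER_DEGREE`.
    """
    lat = np.asarray(lat_center, dtype=float)
    if np.any(np.abs(lat) >= 90):
        raise GridError("cell center latitude must satisfy |lat| < 90")
    side = KM_PER_DEGREE * resolution
    area = side * side * np.cos(np.deg2rad(lat))
    return float(area) if np.isscalar(lat_center) else area


def _nearest_indices(src: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Index of the nearest source coordinate; ties go to the lower value."""
    pos = np.searchsorted(src, targets)
    pos = np.clip(pos, 1, len(src) - 1) if len(src) > 1 else np.zeros_like(pos)
    lo = np.clip(pos - 1, 0, len(src) - 1)
    hi = np.clip(pos, 0, len(src) - 1)
    # strict '<' keeps the lower neighbour on exact ties
    take_hi = np.abs(src[hi] - targets) < np.abs(src[lo] - targets)
    return np.where(take_hi, hi, lo)


def regrid_nearest(grid: EnvGrid, target: GridSpec) -> EnvGrid:
    """Nearest-neighbour regridding between cell-center grids.

    Each target cell takes the value of the source cell whose center is
    nearest; exact distance ties break toward the lower latitude, then the
    lower longitude.
    """
    src = grid.spec
    if (src.lat_min >= target.lat_max or target.lat_min >= src.lat_max
            or src.lon_min >= target.lon_max or target.lon_min >= src.lon_max):
        raise GridError("source and target grids do not overlap")
    ilat = _nearest_indices(src.lat_centers, target.lat_centers)
    ilon = _nearest_indices(src.lon_centers, target.lon_centers)
    values = grid.values[np.ix_(ilat, ilon)]
    return EnvGrid(spec=target, variable=grid.variable, values=values, units=grid.units)


# ---------------------------------------------------------------------------
# NetCDF / GeoTIFF layer I/O

def _spec_from_coords(lat: np.ndarray, lon: np.ndarray) -> GridSpec:
    for name, c in (("lat", lat), ("lon", lon)):
        d = np.diff(c)
        if len(c) < 2 or not (np.all(d > 0) and np.allclose(d, d[0])):
            raise GridError(f"{name} coordinate is not monotone-ascending and regular")
    res = float(lat[1] - lat[0])
    if not np.allclose(np.diff(lon), res):
        raise GridError("lat and lon resolutions differ")
    return GridSpec(
        lat_min=float(lat[0] - res / 2),
        lat_max=float(lat[-1] + res / 2),
        lon_min=float(lon[0] - res / 2),
        lon_max=float(lon[-1] + res / 2),
        resolution=res,
    )


def read_env_layer(path, variable: str | None = None) -> EnvGrid:
    """Read one 2-D environmental field from NetCDF or GeoTIFF.

    NetCDF files need CF-style ``lat``/``lon`` coordinate variables; a
    descending latitude axis is reordered to ascending. GeoTIFFs need the
    ModelPixelScale and ModelTiepoint tags; the GDAL nodata tag maps to NaN.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_geotiff(path, variable)
    try:
        ds = xr.open_dataset(path, engine=_NETCDF_ENGINE)
    except Exception as exc:  # pragma: no cover - passthrough message
        raise GridError(f"unreadable NetCDF file {path}: {exc}") from exc
    with ds:
        if variable is None:
            candidates = [v for v in ds.data_vars if ds[v].ndim == 2]
            if len(candidates) != 1:
                raise GridError(f"{path} holds {len(candidates)} 2-D fields; pass variable=")
            variable = candidates[0]
        if variable not in ds:
            raise GridError(f"{path} has no variable '{variable}'")
        da = ds[variable]
        if "lat" not in da.coords or "lon" not in da.coords:
            raise GridError(f"{path} lacks lat/lon coordinate metadata")
        lat = np.asarray(da["lat"].values, dtype=float)
        if len(lat) > 1 and lat[0] > lat[-1]:
            da = da.isel(lat=slice(None, None, -1))
            lat = np.asarray(da["lat"].values, dtype=float)
        lon = np.asarray(da["lon"].values, dtype=float)
        spec = _spec_from_coords(lat, lon)
        values = np.asarray(da.transpose("lat", "lon").values, dtype=float)
        units = str(da.attrs.get("units", ""))
    return EnvGrid(spec=spec, variable=variable, values=values, units=units)


def write_env_layer(grid: EnvGrid, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        _write_geotiff(grid, path)
        return
    da = xr.DataArray(
        grid.values,
        coords={"lat": grid.spec.lat_centers, "lon": grid.spec.lon_centers},
        dims=("lat", "lon"),
        name=grid.variable,
        attrs={"units": grid.units},
    )
    da.to_dataset().to_netcdf(path, engine=_NETCDF_ENGINE)


def write_env_stack(stack: EnvStack, path) -> None:
    """Write a whole period stack as one multi-variable NetCDF."""
    spec = stack.spec
    ds = xr.Dataset(
        {
            name: (("lat", "lon"), g.values, {"units": g.units})
            for name, g in stack.layers.items()
        },
        coords={"lat": spec.lat_centers, "lon": spec.lon_centers},
        attrs={"period_label": stack.period_label},
    )
    ds.to_netcdf(Path(path), engine=_NETCDF_ENGINE)


def read_env_stack(path) -> EnvStack:
    with xr.open_dataset(Path(path), engine=_NETCDF_ENGINE) as ds:
        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
        spec = _spec_from_coords(lat, lon)
        layers = {
            str(name): EnvGrid(
                spec=spec,
                variable=str(name),
                values=np.asarray(ds[name].transpose("lat", "lon").values, dtype=float),
                units=str(ds[name].attrs.get("units", "")),
            )
            for name in ds.data_vars
        }
        label = str(ds.attrs.get("period_label", ""))
    return EnvStack(period_label=label, layers=layers)


# GeoTIFF tag ids: pixel scale, tiepoint, GDAL nodata.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113
_NODATA = -9999.0


def _write_geotiff(grid: EnvGrid, path: Path) -> None:
    import tifffile

    spec = grid.spec
    data = np.flipud(grid.values).astype(np.float32)  # GeoTIFF rows run north->south
    data = np.where(np.isfinite(data), data, np.float32(_NODATA))
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.resolution, spec.resolution, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.lon_min, spec.lat_max, 0.0)),
        (_TAG_NODATA, "s", 0, str(_NODATA)),
    ]
    tifffile.imwrite(path, data, extratags=extratags, metadata=None)


def _read_geotiff(path: Path, variable: str | None) -> EnvGrid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            tags = {t.code: t.value for t in page.tags.values()}
            data = page.asarray().astype(float)
    except Exception as exc:
        raise GridError(f"unreadable GeoTIFF {path}: {exc}") from exc
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise GridError(f"{path} lacks geographic tags (ModelPixelScale/ModelTiepoint)")
    sx, sy = float(tags[_TAG_PIXEL_SCALE][0]), float(tags[_TAG_PIXEL_SCALE][1])
    tie = tags[_TAG_TIEPOINT]
    lon_min, lat_max = float(tie[3]), float(tie[4])
    if not np.isclose(sx, sy):
        raise GridError("anisotropic pixels not supported")
    n_lat, n_lon = data.shape
    if _TAG_NODATA in tags:
        nodata = float(str(tags[_TAG_NODATA]).strip("\x00 "))
        data = np.where(np.isclose(data, nodata), np.nan, data)
    spec = GridSpec(
        lat_min=lat_max - n_lat * sy,
        lat_max=lat_max,
        lon_min=lon_min,
        lon_max=lon_min + n_lon * sx,
        resolution=sx,
    )
    return EnvGrid(spec=spec, variable=variable or "layer", values=np.flipud(data))


# ---------------------------------------------------------------------------
# tables and polygons

OCCURRENCE_COLUMNS = ["species", "lon", "lat", "year", "source"]


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise GridError(f"occurrence table missing columns: {missing}")
    return df


def write_occurrences(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=OCCURRENCE_COLUMNS)


def read_polygons(path) -> dict[str, "shapely.geometry.base.BaseGeometry"]:  # noqa: F821
    """Read a GeoJSON FeatureCollection into {name: shapely geometry}."""
    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for i, feat in enumerate(gj.get("features", [])):
        name = str(feat.get("properties", {}).get("name", f"feature_{i}"))
        out[name] = shape(feat["geometry"])
    if not out:
        raise GridError(f"{path} contains no features")
    return out


def write_polygons(polygons: dict, path) -> None:
    features = [
        {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}
        for name, geom in polygons.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def mask_from_polygon(polygon, spec: GridSpec, label: str) -> RegionMask:
    """Cell-center-in-polygon (boundary inclusive) region mask."""
    import shapely

    lon, lat = np.meshgrid(spec.lon_centers, spec.lat_centers)
    pts = shapely.points(lon.ravel(), lat.ravel())
    member = shapely.covers(polygon, pts).reshape(spec.shape)
    return RegionMask(spec=spec, member=member, label=label)
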