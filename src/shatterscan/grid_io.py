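"""Grid geometry, conservative regridding, region masks, and NetCDF I/O.

Everything downstream works on a :class:`SmileCube`, a thin wrapper around an
``xarray.DataArray`` with dims ``(member, year, lat, lon)`` holding annual
surface soil moisture for every ensemble member.  This module provides

* :class:`GridSpec` — a rectilinear lat/lon grid with explicit cell bounds,
* :class:`RegionSet` — named, non-overlapping breadbasket masks plus
  cos-latitude area weights,
* first-order conservative regridding between rectilinear grids,
* calendar-year annualization of monthly cubes, and
* CF-style NetCDF round-tripping (NetCDF3 via the scipy backend, so no
  external C library is required).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import xarray as xr
import yaml

__all__ = [
    "GridSpec",
    "RegionSet",
    "SmileCube",
    "GeometryError",
    "FormatError",
    "regrid_conservative",
    "regrid_mask",
    "annual_mean",
    "load_cube",
    "save_cube",
]

CUBE_DIMS = ("member", "year", "lat", "lon")


class GeometryError(ValueError):
    """Raised when grids or regions are geometrically inconsistent."""


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk layout."""


def _bounds_from_centers(centers: np.ndarray) -> np.ndarray:
    """Contiguous cell bounds with interfaces at midpoints between centers."""
    c = np.asarray(centers, dtype=float)
    if c.ndim != 1 or c.size < 1:
        raise GeometryError("coordinate centers must be a non-empty 1-D array")
    if c.size == 1:
        # degenerate single cell: make it 1 degree wide
        return np.array([c[0] - 0.5, c[0] + 0.5])
    if not (np.all(np.diff(c) > 0) or np.all(np.diff(c) < 0)):
        raise GeometryError("coordinate centers must be strictly monotonic")
    mid = 0.5 * (c[:-1] + c[1:])
    first = c[0] - (mid[0] - c[0])
    last = c[-1] + (c[-1] - mid[-1])
    return np.concatenate([[first], mid, [last]])


@dataclass(frozen=True)
class GridSpec:
    """Rectilinear lat/lon grid defined by cell-center coordinates.

    Bounds are taken at midpoints between centers (extrapolated at the edges)
    unless given explicitly; they must tile the domain without overlap.
    Longitudes are normalized to [-180, 180).
    """

    lat: np.ndarray
    lon: np.ndarray
    lat_bounds: np.ndarray = field(default=None)  # type: ignore[assignment]
    lon_bounds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        lon = ((lon + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        lb = self.lat_bounds
        object.__setattr__(
            self, "lat_bounds",
            np.asarray(lb, float) if lb is not None else _bounds_from_centers(lat),
        )
        gb = self.lon_bounds
        object.__setattr__(
            self, "lon_bounds",
            np.asarray(gb, float) if gb is not None else _bounds_from_centers(lon),
        )
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lat_bounds) > 90 + 1e-9):
            raise GeometryError("latitudes must lie within [-90, 90]")
        object.__setattr__(
            self, "lat_bounds", np.clip(self.lat_bounds, -90.0, 90.0)
        )

    @classmethod
    def uniform(cls, res: float = 2.5, lat_range=(-90.0, 90.0), lon_range=(-180.0, 180.0)) -> "GridSpec":
        """Uniform grid of resolution ``res`` degrees with cell centers offset by res/2."""
        lat = np.arange(lat_range[0] + res / 2, lat_range[1], res)
        lon = np.arange(lon_range[0] + res / 2, lon_range[1], res)
        return cls(lat=lat, lon=lon)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    def cell_area_weights(self) -> np.ndarray:
        """Per-cell area weights proportional to true spherical cell area.

        Computed from sin-latitude bound differences times longitudinal width,
        which reduces to cos(latitude) for narrow uniform bands.
        """
        lat_w = np.abs(np.diff(np.sin(np.radians(self.lat_bounds))))
        lon_w = np.abs(np.diff(self.lon_bounds))
        return np.outer(lat_w, lon_w)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )


@dataclass
class RegionSet:
    """Named breadbasket masks over a grid, mutually exclusive by construction.

    ``weights`` are area weights shared by all area-fraction computations;
    ``global_mask`` (the union of all regions) defines the global breadbasket.
    """

    grid: GridSpec
    masks: dict[str, np.ndarray]
    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = self.grid.shape
        total = np.zeros(shape, dtype=int)
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != shape:
                raise GeometryError(f"mask for region {name!r} has shape {m.shape}, grid is {shape}")
            if not m.any():
                raise GeometryError(f"region {name!r} has an empty cell set")
            self.masks[name] = m
            total += m
        if np.any(total > 1):
            raise GeometryError("regions overlap: a cell may belong to at most one breadbasket")
        if self.weights is None:
            self.weights = self.grid.cell_area_weights()
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights[self.global_mask] <= 0):
            raise GeometryError("area weights must be positive on region cells")

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    @property
    def global_mask(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out

    def mask_for(self, scope: str) -> np.ndarray:
        if scope == "global":
            return self.global_mask
        if scope not in self.masks:
            raise KeyError(f"unknown scope {scope!r}; known: {self.names + ['global']}")
        return self.masks[scope]

    def region_index(self) -> np.ndarray:
        """Integer map: -1 outside all regions, else index into :attr:`names`."""
        idx = np.full(self.grid.shape, -1, dtype=int)
        for i, m in enumerate(self.masks.values()):
            idx[m] = i
        return idx

    @classmethod
    def from_boxes(cls, grid: GridSpec, boxes: Mapping[str, Sequence[float]]) -> "RegionSet":
        """Build masks from lat/lon boxes ``{name: (lat0, lat1, lon0, lon1)}``."""
        masks = {}
        for name, (lat0, lat1, lon0, lon1) in boxes.items():
            latm = (grid.lat >= min(lat0, lat1)) & (grid.lat <= max(lat0, lat1))
            lonm = (grid.lon >= min(lon0, lon1)) & (grid.lon <= max(lon0, lon1))
            masks[name] = np.outer(latm, lonm)
        return cls(grid=grid, masks=masks)

    @classmethod
    def from_file(cls, grid: GridSpec, path) -> "RegionSet":
        """Read region definitions from a YAML file.

        Schema: ``regions: {name: {box: [lat0, lat1, lon0, lon1]}}`` or
        ``{name: {cells: [[i, j], ...]}}`` with 0-based (lat, lon) indices.
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        masks: dict[str, np.ndarray] = {}
        boxes: dict[str, Sequence[float]] = {}
        for name, spec in doc["regions"].items():
            if "box" in spec:
                boxes[name] = spec["box"]
            elif "cells" in spec:
                m = np.zeros(grid.shape, dtype=bool)
                for i, j in spec["cells"]:
                    m[i, j] = True
                masks[name] = m
            else:
                raise FormatError(f"region {name!r} needs a 'box' or 'cells' entry")
        if boxes:
            for name, m in cls.from_boxes(grid, boxes).masks.items():
                masks[name] = m
        return cls(grid=grid, masks=masks)


@dataclass
class SmileCube:
    """Annual gridded soil-moisture ensemble: values per (member, year, cell).

    ``provenance`` records the transformation history (generation parameters,
    regridding, detrending experiments) as free-text lines.
    """

    data: xr.DataArray
    units: str = "kg m-2"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if tuple(self.data.dims) != CUBE_DIMS:
            raise FormatError(f"cube dims must be {CUBE_DIMS}, got {tuple(self.data.dims)}")

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.data.year.values)

    @property
    def n_members(self) -> int:
        return self.data.sizes["member"]

    @property
    def grid(self) -> GridSpec:
        return GridSpec(lat=self.data.lat.values, lon=self.data.lon.values)

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    def sel_years(self, start: int, end: int) -> "SmileCube":
        """Subset to the inclusive year range [start, end]."""
        sub = self.data.sel(year=slice(start, end))
        return SmileCube(sub, units=self.units, provenance=list(self.provenance))

    def with_values(self, values: np.ndarray, note: str | None = None) -> "SmileCube":
        da = self.data.copy(data=np.asarray(values, dtype=float))
        prov = list(self.provenance) + ([note] if note else [])
        return SmileCube(da, units=self.units, provenance=prov)


# ---------------------------------------------------------------------------
# conservative regridding


def _overlap_matrix(dst_b: np.ndarray, src_b: np.ndarray, metric=None) -> np.ndarray:
    """Interval-overlap weights W[d, s] between two 1-D bound sets.

    ``metric`` maps bound coordinates to the measure in which overlap is
    computed (sin(lat) for true spherical area along latitude).
    """
    db = np.sort(np.asarray(dst_b, float))
    sb = np.sort(np.asarray(src_b, float))
    if metric is not None:
        db, sb = metric(db), metric(sb)
    lo = np.maximum(db[:-1, None], sb[None, :-1])
    hi = np.minimum(db[1:, None], sb[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def regrid_conservative(field: np.ndarray | xr.DataArray, src: GridSpec, dst: GridSpec) -> np.ndarray:
    """First-order conservative regridding between rectilinear lat/lon grids.

    Each destination value is the area-overlap-weighted mean of the source
    values it covers, so the global area-weighted mean is conserved wherever
    the destination grid covers the source domain.  Overlap areas factor into
    independent latitude (measured in sin-latitude, i.e. true spherical area)
    and longitude contributions.
    """
    arr = np.asarray(field, dtype=float)
    if arr.shape[-2:] != src.shape:
        raise GeometryError(f"field trailing shape {arr.shape[-2:]} does not match source grid {src.shape}")
    if not np.all(np.isfinite(arr)):
        raise GeometryError("field must be finite on the source grid")
    wlat = _overlap_matrix(dst.lat_bounds, src.lat_bounds,
                           metric=lambda b: np.sin(np.radians(b)))
    wlon = _overlap_matrix(dst.lon_bounds, src.lon_bounds)
    # orient rows/cols to match center ordering (bounds were sorted)
    if np.any(np.diff(dst.lat) < 0):
        wlat = wlat[::-1]
    if np.any(np.diff(src.lat) < 0):
        wlat = wlat[:, ::-1]
    if np.any(np.diff(dst.lon) < 0):
        wlon = wlon[::-1]
    if np.any(np.diff(src.lon) < 0):
        wlon = wlon[:, ::-1]
    area = wlat @ np.ones((src.shape[0], src.shape[1])) @ wlon.T
    if np.all(area <= 0):
        raise GeometryError("source and destination domains do not overlap")
    num = np.einsum("ab,...bc,dc->...ad", wlat, arr, wlon)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / area
    out[..., area <= 0] = np.nan
    return out


def regrid_mask(mask: np.ndarray, src: GridSpec, dst: GridSpec, threshold: float = 0.5) -> np.ndarray:
    """Regrid a boolean mask: destination cell is in-region if >= ``threshold``
    of its area overlaps source region cells."""
    frac = regrid_conservative(np.asarray(mask, dtype=float), src, dst)
    return np.nan_to_num(frac, nan=0.0) >= threshold


# ---------------------------------------------------------------------------
# annualization


def annual_mean(monthly: xr.DataArray) -> SmileCube:
    """Collapse a monthly cube to calendar-year means (equal month weights).

    Accepts dims ``(member, time, lat, lon)`` where the ``time`` dim carries
    integer ``year`` and ``month`` coordinates, or ``(member, year, month,
    lat, lon)``.  Every year must have exactly 12 months.
    """
    if "month" in monthly.dims:
        if monthly.sizes["month"] != 12:
            raise FormatError(f"expected 12 months, got {monthly.sizes['month']}")
        annual = monthly.mean("month")
        annual = annual.transpose(*CUBE_DIMS)
        return SmileCube(annual, units=str(monthly.attrs.get("units", "")),
                         provenance=["annual mean of monthly input"])
    if "time" not in monthly.dims:
        raise FormatError("monthly cube needs a 'month' or 'time' dimension")
    years = np.asarray(monthly["year"].values)
    uniq, counts = np.unique(years, return_counts=True)
    bad = uniq[counts != 12]
    if bad.size:
        raise FormatError(f"incomplete calendar year(s): {bad.tolist()} (need 12 months each)")
    annual = monthly.groupby("year").mean("time")
    annual = annual.transpose(*CUBE_DIMS)
    return SmileCube(annual, units=str(monthly.attrs.get("units", "")),
                     provenance=["annual mean of monthly input"])


# ---------------------------------------------------------------------------
# NetCDF I/O (NetCDF3 via the scipy backend; no external C dependency)


def save_cube(cube: SmileCube, path, var_name: str = "mrsos") -> None:
    ds = cube.data.to_dataset(name=var_name)
    ds[var_name].attrs["units"] = cube.units
    ds.attrs["provenance"] = "\n".join(cube.provenance)
    enc = {var_name: {"dtype": "float64"}}
    ds = ds.assign_coords(member=ds.member.astype("int32"), year=ds.year.astype("int32"))
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def load_cube(path, var_name: str = "mrsos", annualize: bool = False) -> SmileCube:
    """Load a cube; a missing ``member`` dim is treated as a 1-member ensemble
    (with a warning), and a monthly ``time`` axis is annualized only when
    ``annualize=True``."""
    ds = xr.open_dataset(path, engine="scipy").load()
    if var_name not in ds:
        raise FormatError(f"variable {var_name!r} not found; file has {list(ds.data_vars)}")
    da = ds[var_name]
    for coord in ("lat", "lon"):
        if coord not in da.coords:
            raise FormatError(f"missing coordinate {coord!r}; expected dims (member, year|time, lat, lon)")
    if "member" not in da.dims:
        warnings.warn("input has no 'member' dimension; treating as a 1-member ensemble")
        da = da.expand_dims(member=[0])
    if "time" in da.dims:
        if not annualize:
            raise FormatError("input has a monthly 'time' axis; pass annualize=True to take calendar-year means")
        cube = annual_mean(da)
        cube.units = str(da.attrs.get("units", cube.units))
        return cube
    if "year" not in da.dims:
        raise FormatError("missing 'year' (or 'time') dimension")
    da = da.transpose(*CUBE_DIMS)
    prov = [ln for ln in str(ds.attrs.get("provenance", "")).split("\n") if ln]
    return SmileCube(da, units=str(da.attrs.get("units", "")), provenance=prov)
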