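"""Percentile-threshold drought classification and drought-area series.

A grid cell is under drought in a given year when its annual surface soil
moisture falls strictly below the local percentile threshold (default the
20th percentile) of the distribution pooled over all ensemble members during
a preindustrial reference period (default 1850-1899).  The drought area of a
scope (one breadbasket region, or the global union) is the area-weighted
percentage of its cells under drought; the global annual drought area is the
fraction of the whole breadbasket under drought.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import xarray as xr

from .grid_io import GeometryError, RegionSet, SmileCube

__all__ = [
    "BaselineStats",
    "AreaSeries",
    "fit_baseline",
    "classify_drought",
    "drought_area",
    "drought_intensity",
]


@dataclass
class BaselineStats:
    """Per-cell reference-period statistics from the pooled ensemble sample.

    ``threshold`` is the empirical percentile (linear interpolation between
    order statistics) of the members x reference-years pool; ``mean`` and
    ``sd`` (sample SD, n-1) come from the same pool and standardize drought
    intensities.  Cells with ``sd == 0`` are flagged degenerate.
    """

    threshold: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    ref_period: tuple[int, int]
    percentile: float
    lat: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    lon: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def degenerate(self) -> np.ndarray:
        return self.sd == 0


@dataclass
class AreaSeries:
    """Per-(member, year) drought area in percent for one scope.

    ``denominator`` records whether the percentage is relative to the scope's
    own area ("regional") or to the total breadbasket area ("global")."""

    values: xr.DataArray  # dims (member, year), percent in [0, 100]
    scope: str
    denominator: Literal["regional", "global"]

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.values.year.values)

    @property
    def n_members(self) -> int:
        return self.values.sizes["member"]

    def member(self, m: int) -> np.ndarray:
        return self.values.isel(member=m).values

    def sel_years(self, start: int, end: int) -> "AreaSeries":
        return AreaSeries(self.values.sel(year=slice(start, end)), self.scope, self.denominator)


def fit_baseline(
    cube: SmileCube,
    ref_period: tuple[int, int] = (1850, 1899),
    percentile: float = 20.0,
) -> BaselineStats:
    """Fit per-cell percentile thresholds on the pooled reference sample.

    The pool at each cell is all members x all reference years; the threshold
    is the linear-interpolation empirical percentile of that pool.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    years = cube.years
    if ref_period[0] < years.min() or ref_period[1] > years.max():
        raise ValueError(f"reference period {ref_period} outside data span "
                         f"({years.min()}-{years.max()})")
    ref = cube.sel_years(*ref_period).values  # (member, year, lat, lon)
    pooled = ref.reshape(-1, *ref.shape[2:])
    thr = np.percentile(pooled, percentile, axis=0)
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1) if pooled.shape[0] > 1 else np.zeros_like(mean)
    return BaselineStats(
        threshold=thr, mean=mean, sd=sd,
        ref_period=tuple(ref_period), percentile=float(percentile),
        lat=cube.data.lat.values, lon=cube.data.lon.values,
    )


def classify_drought(cube: SmileCube, baseline: BaselineStats) -> xr.DataArray:
    """Boolean drought mask per (member, year, cell): value strictly below
    the local threshold.  Values exactly at the threshold are not drought."""
    if baseline.threshold.shape != cube.grid.shape:
        raise GeometryError(
            f"baseline grid {baseline.threshold.shape} does not match cube grid {cube.grid.shape}")
    return (cube.data < xr.DataArray(baseline.threshold, dims=("lat", "lon"),
                                     coords={"lat": cube.data.lat, "lon": cube.data.lon}))


def drought_area(
    mask: xr.DataArray,
    regions: RegionSet,
    scope: str = "global",
    denominator: Literal["regional", "global"] = "regional",
    equal_cell_weights: bool = False,
) -> AreaSeries:
    """Area-weighted drought area (%) per (member, year) for a scope.

    The numerator sums area weights over drought cells inside the scope; the
    denominator sums weights over the scope's cells ("regional") or over the
    whole breadbasket union ("global").  ``equal_cell_weights=True`` counts
    cells instead of weighting by area.
    """
    if denominator not in ("regional", "global"):
        raise ValueError(f"denominator must be 'regional' or 'global', got {denominator!r}")
    scope_mask = regions.mask_for(scope)
    denom_mask = regions.global_mask if denominator == "global" else scope_mask
    w = np.ones(regions.grid.shape) if equal_cell_weights else regions.weights
    w_scope = np.where(scope_mask, w, 0.0)
    denom = w[denom_mask].sum()
    m = mask.values  # (member, year, lat, lon)
    num = np.einsum("mtij,ij->mt", m.astype(float), w_scope)
    vals = 100.0 * num / denom
    da = xr.DataArray(vals, dims=("member", "year"),
                      coords={"member": mask.member, "year": mask.year})
    return AreaSeries(values=da, scope=scope, denominator=denominator)


def drought_intensity(
    cube: SmileCube,
    mask: xr.DataArray,
    baseline: BaselineStats,
    regions: RegionSet,
    scope: str = "global",
) -> xr.DataArray:
    """Area-weighted mean standardized anomaly over drought cells, in sigma
    units, per (member, year); NaN when no cell in the scope is under drought.

    Anomalies are relative to the pooled reference mean and standardized by
    the pooled reference SD at each cell; a drought cell with zero reference
    SD is a hard error (the standardization is undefined there).
    """
    scope_mask = regions.mask_for(scope)
    m = mask.values & scope_mask  # (member, year, lat, lon)
    bad = m & (baseline.sd == 0.0)
    if bad.any():
        ij = np.argwhere(bad.any(axis=(0, 1)))[0]
        raise FloatingPointError(
            f"zero reference-period SD at drought cell (lat_idx={ij[0]}, lon_idx={ij[1]}); "
            "intensity is undefined there")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (cube.values - baseline.mean) / baseline.sd
    z = np.where(m, np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
    w = np.where(scope_mask, regions.weights, 0.0)
    num = np.einsum("mtij,ij->mt", z, w)
    den = np.einsum("mtij,ij->mt", m.astype(float), w)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return xr.DataArray(out, dims=("member", "year"),
                        coords={"member": cube.data.member, "year": cube.data.year})
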