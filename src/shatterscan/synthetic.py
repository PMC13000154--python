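"""Synthetic single-model initial-condition large ensembles (SMILEs).

Generates annual gridded soil-moisture ensembles whose members differ only by
internal variability, with prescribed per-region long-term changes in the
mean and in the standard deviation.  The construction is

    value(m, y, c) = baseline_mean(c) + mean_offset(region(c), y)
                     + sd_factor(region(c), y) * baseline_sd(c) * eps(m, y, c)

where ``eps`` is a zero-mean unit-variance Gaussian process, spatially
correlated with an exponential correlogram in degree distance and AR(1) in
time.  The AR(1) recursion is applied to the already spatially correlated
innovations, before trend/scale injection, so detrending experiments see
realistic persistence.

Every member draws from its own counter-derived random stream, so adding
members never reshuffles the noise of earlier ones, and identical
(config, seed) pairs reproduce bit-identical cubes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import xarray as xr
import yaml

from .grid_io import CUBE_DIMS, GridSpec, RegionSet, SmileCube

__all__ = [
    "SyntheticConfig",
    "ConfigurationError",
    "generate_smile",
    "stationary_variant",
    "as_monthly",
    "ramp",
    "piecewise_linear",
    "constant",
]


class ConfigurationError(ValueError):
    """Raised for invalid synthetic-ensemble configurations."""


# -- trend helpers -----------------------------------------------------------

def ramp(start_year: int, rate: float, base: float = 0.0) -> Callable[[np.ndarray], np.ndarray]:
    """Offset that is ``base`` before ``start_year`` and then changes by
    ``rate`` (units per year) each year: the canonical drying/wetting trend."""
    def f(years: np.ndarray) -> np.ndarray:
        y = np.asarray(years, dtype=float)
        return base + rate * np.clip(y - start_year, 0.0, None)
    return f


def piecewise_linear(points: Mapping[int, float]) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-linear offset through ``{year: value}`` knots, constant
    extrapolation outside the knot range."""
    xs = np.array(sorted(points), dtype=float)
    ys = np.array([points[int(x)] for x in xs], dtype=float)
    def f(years: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(years, dtype=float), xs, ys)
    return f


def constant(value: float) -> Callable[[np.ndarray], np.ndarray]:
    def f(years: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(years).shape, float(value))
    return f


_ZERO = constant(0.0)
_ONE = constant(1.0)


@dataclass
class SyntheticConfig:
    """Recipe for a synthetic SMILE.

    Parameters
    ----------
    n_members : number of ensemble members.
    years : inclusive (first, last) year span; default 1850-2099.
    grid : grid geometry.
    regions : breadbasket masks; trends apply only inside their cells.
    baseline_mean, baseline_sd : scalar or per-cell field, soil-moisture units.
    mean_trend : per-region additive offset as a function of year
        (units; see :func:`ramp` / :func:`piecewise_linear`); zero where a
        region is not listed, and always zero outside all regions.
    sd_factor : per-region dimensionless multiplier (> 0) on the noise SD;
        one where not listed.
    spatial_corr_length : e-folding length (degrees) of the exponential
        spatial correlogram; 0 means independent cells.
    ar1_coef : lag-1 autocorrelation of the noise, in [0, 1).
    seed : master seed; member streams are derived from (seed, member).
    """

    n_members: int
    grid: GridSpec
    regions: RegionSet
    years: tuple[int, int] = (1850, 2099)
    baseline_mean: float | np.ndarray = 30.0
    baseline_sd: float | np.ndarray = 2.0
    mean_trend: dict[str, Callable[[np.ndarray], np.ndarray]] = field(default_factory=dict)
    sd_factor: dict[str, Callable[[np.ndarray], np.ndarray]] = field(default_factory=dict)
    spatial_corr_length: float = 5.0
    ar1_coef: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_members < 1:
            raise ConfigurationError("n_members must be >= 1")
        if self.years[1] < self.years[0]:
            raise ConfigurationError(f"invalid year range {self.years}")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ConfigurationError("ar1_coef must lie in [0, 1)")
        if self.spatial_corr_length < 0:
            raise ConfigurationError("spatial_corr_length must be >= 0")
        if self.regions.grid != self.grid:
            raise ConfigurationError("regions are defined on a different grid")
        sd = np.broadcast_to(np.asarray(self.baseline_sd, float), self.grid.shape)
        if np.any(sd <= 0):
            raise ConfigurationError("baseline_sd must be > 0 everywhere")
        yrs = self.year_axis()
        for name, f in self.sd_factor.items():
            if name not in self.regions.masks:
                raise ConfigurationError(f"sd_factor names unknown region {name!r}")
            if np.any(np.asarray(f(yrs)) <= 0):
                raise ConfigurationError(f"sd_factor for region {name!r} must be > 0 for all years")
        for name in self.mean_trend:
            if name not in self.regions.masks:
                raise ConfigurationError(f"mean_trend names unknown region {name!r}")

    def year_axis(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        """Build a config from a declarative YAML file.

        Schema (all trends are optional)::

            n_members: 20
            years: [1850, 2099]
            seed: 7
            grid: {n_lat: 12, n_lon: 24, lat_range: [-60, 60], lon_range: [-180, 180]}
            baseline_mean: 30.0
            baseline_sd: 2.0
            spatial_corr_length: 5.0
            ar1_coef: 0.3
            regions: {A: {box: [30, 50, -120, -80]}, ...}
            mean_trend: {A: {ramp: {start_year: 2000, rate: -0.02}}}
            sd_factor: {A: {ramp: {start_year: 2000, rate: 0.005, base: 1.0}}}
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        g = doc["grid"]
        lat_range = g.get("lat_range", [-90, 90])
        lon_range = g.get("lon_range", [-180, 180])
        lat = np.linspace(lat_range[0], lat_range[1], g["n_lat"] + 1)
        lat = 0.5 * (lat[:-1] + lat[1:])
        lon = np.linspace(lon_range[0], lon_range[1], g["n_lon"] + 1)
        lon = 0.5 * (lon[:-1] + lon[1:])
        grid = GridSpec(lat=lat, lon=lon)
        regions = RegionSet.from_boxes(grid, {k: v["box"] for k, v in doc["regions"].items()})

        def parse_trends(section) -> dict:
            out = {}
            for name, spec in (doc.get(section) or {}).items():
                if "ramp" in spec:
                    out[name] = ramp(**spec["ramp"])
                elif "piecewise" in spec:
                    out[name] = piecewise_linear({int(k): v for k, v in spec["piecewise"].items()})
                elif "constant" in spec:
                    out[name] = constant(spec["constant"])
                else:
                    raise ConfigurationError(f"{section}[{name!r}] needs ramp/piecewise/constant")
            return out

        return cls(
            n_members=int(doc["n_members"]),
            years=tuple(doc.get("years", (1850, 2099))),
            grid=grid,
            regions=regions,
            baseline_mean=doc.get("baseline_mean", 30.0),
            baseline_sd=doc.get("baseline_sd", 2.0),
            mean_trend=parse_trends("mean_trend"),
            sd_factor=parse_trends("sd_factor"),
            spatial_corr_length=float(doc.get("spatial_corr_length", 5.0)),
            ar1_coef=float(doc.get("ar1_coef", 0.3)),
            seed=int(doc.get("seed", 0)),
        )


def _spatial_cholesky(grid: GridSpec, corr_length: float) -> np.ndarray | None:
    """Cholesky factor of the exponential spatial correlation over all cells.

    Distance is great-circle-approximated in degrees:
    d = sqrt(dlat^2 + (dlon * cos(mean lat))^2), with longitudinal wraparound.
    Returns None for independent cells (corr_length == 0).
    """
    if corr_length == 0:
        return None
    lat2, lon2 = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    lat_f, lon_f = lat2.ravel(), lon2.ravel()
    dlat = lat_f[:, None] - lat_f[None, :]
    dlon = np.abs(lon_f[:, None] - lon_f[None, :])
    dlon = np.minimum(dlon, 360.0 - dlon)
    coslat = np.cos(np.radians(0.5 * (lat_f[:, None] + lat_f[None, :])))
    dist = np.sqrt(dlat**2 + (dlon * coslat) ** 2)
    corr = np.exp(-dist / corr_length)
    corr[np.diag_indices_from(corr)] += 1e-10  # jitter for numerical PD
    return np.linalg.cholesky(corr)


def _member_noise(config: SyntheticConfig, member: int, chol: np.ndarray | None) -> np.ndarray:
    """Unit-variance spatially correlated AR(1) noise for one member,
    shape (n_years, n_lat, n_lon)."""
    n_years = config.years[1] - config.years[0] + 1
    shape = config.grid.shape
    n_cells = shape[0] * shape[1]
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((config.seed, member))))
    z = rng.standard_normal((n_years, n_cells))
    if chol is not None:
        z = z @ chol.T
    phi = config.ar1_coef
    if phi > 0:
        eps = np.empty_like(z)
        eps[0] = z[0]  # stationary start: marginal variance 1 throughout
        fac = math.sqrt(1.0 - phi * phi)
        for t in range(1, n_years):
            eps[t] = phi * eps[t - 1] + fac * z[t]
        z = eps
    return z.reshape(n_years, *shape)


def generate_smile(config: SyntheticConfig) -> SmileCube:
    """Generate the synthetic ensemble described by ``config``.

    Deterministic in (config, seed); members are generated from independent
    counter-derived streams.
    """
    config.validate()
    years = config.year_axis()
    n_years = years.size
    shape = config.grid.shape
    base_mean = np.broadcast_to(np.asarray(config.baseline_mean, float), shape)
    base_sd = np.broadcast_to(np.asarray(config.baseline_sd, float), shape)

    # per-year fields of the injected mean offset and SD multiplier
    mean_off = np.zeros((n_years,) + shape)
    sd_mult = np.ones((n_years,) + shape)
    for name, mask in config.regions.masks.items():
        off = np.asarray(config.mean_trend.get(name, _ZERO)(years), dtype=float)
        fac = np.asarray(config.sd_factor.get(name, _ONE)(years), dtype=float)
        mean_off[:, mask] = off[:, None]
        sd_mult[:, mask] = fac[:, None]

    chol = _spatial_cholesky(config.grid, config.spatial_corr_length)
    values = np.empty((config.n_members, n_years) + shape)
    for m in range(config.n_members):
        eps = _member_noise(config, m, chol)
        values[m] = base_mean + mean_off + sd_mult * base_sd * eps

    da = xr.DataArray(
        values,
        dims=CUBE_DIMS,
        coords={
            "member": np.arange(config.n_members),
            "year": years,
            "lat": config.grid.lat,
            "lon": config.grid.lon,
        },
        name="mrsos",
    )
    prov = [
        f"synthetic SMILE: {config.n_members} members, years {config.years[0]}-{config.years[1]}, "
        f"seed {config.seed}, ar1 {config.ar1_coef}, corr_length {config.spatial_corr_length} deg",
    ]
    return SmileCube(da, units="kg m-2", provenance=prov)


def stationary_variant(config: SyntheticConfig) -> SyntheticConfig:
    """Return the same config with all mean trends zeroed and all SD factors
    pinned to one; seed and noise structure are preserved."""
    return replace(config, mean_trend={}, sd_factor={})


def as_monthly(cube: SmileCube) -> xr.DataArray:
    """Expand an annual cube into 12 equal-value months per year, for
    exercising the annualization path."""
    monthly = cube.data.expand_dims(month=np.arange(1, 13), axis=2)
    monthly = monthly.transpose("member", "year", "month", "lat", "lon")
    monthly.attrs["units"] = cube.units
    return monthly
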