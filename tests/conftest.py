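import numpy as np
import pytest
import xarray as xr

from shatterscan import (GridSpec, RegionSet, SmileCube, SyntheticConfig,
                         generate_smile)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """6 x 12 grid (20 x 30 degree cells) between 60S and 60N."""
    lat = np.arange(-50.0, 60.0, 20.0)
    lon = np.arange(-165.0, 180.0, 30.0)
    return GridSpec(lat=lat, lon=lon)


@pytest.fixture(scope="session")
def two_regions(small_grid) -> RegionSet:
    boxes = {"A": (-60, 0, -180, 0), "B": (0, 60, 0, 180)}
    return RegionSet.from_boxes(small_grid, boxes)


@pytest.fixture(scope="session")
def stationary_config(small_grid, two_regions) -> SyntheticConfig:
    return SyntheticConfig(
        n_members=12, grid=small_grid, regions=two_regions,
        years=(1850, 2099), baseline_mean=30.0, baseline_sd=2.0,
        spatial_corr_length=0.0, ar1_coef=0.0, seed=99,
    )


@pytest.fixture(scope="session")
def stationary_cube(stationary_config) -> SmileCube:
    return generate_smile(stationary_config)


def make_cube(values: np.ndarray, years=None) -> SmileCube:
    """Wrap a raw (member, year, lat, lon) array into a SmileCube with
    placeholder equatorial coordinates (equal-area cells)."""
    m, y, nlat, nlon = values.shape
    if years is None:
        years = np.arange(1850, 1850 + y)
    half = nlat * 10.0 / 2
    lat = np.arange(-half + 5.0, half, 10.0)
    lon = np.arange(0.0, nlon * 10.0, 10.0) - 180.0 + 5.0
    da = xr.DataArray(
        np.asarray(values, float), dims=("member", "year", "lat", "lon"),
        coords={"member": np.arange(m), "year": np.asarray(years), "lat": lat, "lon": lon})
    return SmileCube(da)
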