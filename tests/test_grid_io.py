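"""Grid geometry, conservative regridding, annualization, and NetCDF I/O."""

import numpy as np
import pytest
import xarray as xr

from shatterscan import (GridSpec, RegionSet, annual_mean, load_cube,
                         regrid_conservative, regrid_mask, save_cube)
from shatterscan.grid_io import FormatError, GeometryError
from shatterscan.synthetic import as_monthly
from conftest import make_cube


def brute_force_regrid(field, src: GridSpec, dst: GridSpec):
    """Independent oracle: explicit per-cell-pair rectangle overlap in
    (sin lat) x lon measure, triple loop."""
    out = np.zeros(dst.shape)
    areas = np.zeros(dst.shape)
    slb, sgb = np.sort(src.lat_bounds), np.sort(src.lon_bounds)
    dlb, dgb = np.sort(dst.lat_bounds), np.sort(dst.lon_bounds)
    for i in range(dst.shape[0]):
        for j in range(dst.shape[1]):
            for a in range(src.shape[0]):
                for b in range(src.shape[1]):
                    dy = max(0.0, min(np.sin(np.radians(dlb[i + 1])), np.sin(np.radians(slb[a + 1])))
                             - max(np.sin(np.radians(dlb[i])), np.sin(np.radians(slb[a]))))
                    dx = max(0.0, min(dgb[j + 1], sgb[b + 1]) - max(dgb[j], sgb[b]))
                    out[i, j] += dy * dx * field[a, b]
                    areas[i, j] += dy * dx
    return out / areas


def test_constant_field_is_preserved(small_grid):
    dst = GridSpec.uniform(40.0, (-60, 60), (-180, 180))
    field = np.full(small_grid.shape, 3.7)
    out = regrid_conservative(field, small_grid, dst)
    np.testing.assert_allclose(out, 3.7)


def test_equal_area_merge_is_plain_mean():
    """2x2 equal-area cells (1,2,3,4) merged into one -> 2.5."""
    src = GridSpec(lat=np.array([-5.0, 5.0]), lon=np.array([-5.0, 5.0]))
    dst = GridSpec(lat=np.array([0.0]), lon=np.array([0.0]),
                   lat_bounds=np.array([-10.0, 10.0]), lon_bounds=np.array([-10.0, 10.0]))
    out = regrid_conservative(np.array([[1.0, 2.0], [3.0, 4.0]]), src, dst)
    np.testing.assert_allclose(out, [[2.5]])


def test_matches_brute_force_overlap_oracle():
    rng = np.random.default_rng(0)
    src = GridSpec(lat=np.linspace(-52, 52, 5), lon=np.linspace(-150, 150, 7))
    dst = GridSpec(lat=np.linspace(-45, 45, 4), lon=np.linspace(-120, 120, 5))
    field = rng.normal(size=src.shape)
    np.testing.assert_allclose(regrid_conservative(field, src, dst),
                               brute_force_regrid(field, src, dst), rtol=1e-12)


def test_global_mean_is_conserved():
    rng = np.random.default_rng(1)
    src = GridSpec(lat=np.linspace(-80, 80, 9), lon=np.linspace(-160, 160, 12))
    # destination covering the full source domain
    dst = GridSpec(lat=np.linspace(-70, 70, 5), lon=np.linspace(-150, 150, 6),
                   lat_bounds=np.linspace(np.sort(src.lat_bounds)[0], np.sort(src.lat_bounds)[-1], 6),
                   lon_bounds=np.linspace(np.sort(src.lon_bounds)[0], np.sort(src.lon_bounds)[-1], 7))
    field = rng.normal(size=src.shape)

    def weighted_mean(f, g):
        w = g.cell_area_weights()
        return (f * w).sum() / w.sum()

    out = regrid_conservative(field, src, dst)
    assert abs(weighted_mean(out, dst) - weighted_mean(field, src)) < 1e-10


def test_regridding_is_linear():
    rng = np.random.default_rng(2)
    src = GridSpec(lat=np.linspace(-40, 40, 6), lon=np.linspace(-90, 90, 8))
    dst = GridSpec(lat=np.linspace(-30, 30, 3), lon=np.linspace(-60, 60, 4))
    x, y = rng.normal(size=src.shape), rng.normal(size=src.shape)
    lhs = regrid_conservative(2.0 * x - 3.0 * y, src, dst)
    rhs = 2.0 * regrid_conservative(x, src, dst) - 3.0 * regrid_conservative(y, src, dst)
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def test_disjoint_domains_raise():
    src = GridSpec(lat=np.array([-50.0, -40.0]), lon=np.array([-50.0, -40.0]))
    dst = GridSpec(lat=np.array([40.0, 50.0]), lon=np.array([40.0, 50.0]))
    with pytest.raises(GeometryError):
        regrid_conservative(np.ones(src.shape), src, dst)


def test_nonfinite_field_rejected(small_grid):
    field = np.ones(small_grid.shape)
    field[0, 0] = np.nan
    with pytest.raises(GeometryError):
        regrid_conservative(field, small_grid, small_grid)


def test_mask_regridding_majority_rule():
    src = GridSpec(lat=np.array([-5.0, 5.0]), lon=np.array([-5.0, 5.0]))
    dst = GridSpec(lat=np.array([0.0]), lon=np.array([0.0]),
                   lat_bounds=np.array([-10.0, 10.0]), lon_bounds=np.array([-10.0, 10.0]))
    # 2 of 4 equal-area cells -> exactly 50% coverage -> in-region at threshold 0.5
    mask = np.array([[True, True], [False, False]])
    assert regrid_mask(mask, src, dst)[0, 0]
    assert not regrid_mask(np.array([[True, False], [False, False]]), src, dst)[0, 0]


def test_area_weights_follow_cos_latitude():
    g = GridSpec.uniform(2.5, (-90, 90), (-180, 180))
    w = g.cell_area_weights()[:, 0]
    ratio = w / np.cos(np.radians(g.lat))
    assert np.ptp(ratio) / ratio.mean() < 1e-3


# -- annualization -----------------------------------------------------------


def test_annual_mean_of_equal_months_is_identity(stationary_cube):
    monthly = as_monthly(stationary_cube)
    annual = annual_mean(monthly)
    np.testing.assert_allclose(annual.values, stationary_cube.values, rtol=1e-12)


def test_annual_mean_of_month_index():
    cube = make_cube(np.zeros((1, 2, 1, 1)))
    monthly = as_monthly(cube) + xr.DataArray(np.arange(1, 13), dims="month")
    np.testing.assert_allclose(annual_mean(monthly).values, 6.5)


def test_annual_mean_matches_loop_oracle():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=(2, 3, 12, 2, 2))
    da = xr.DataArray(vals, dims=("member", "year", "month", "lat", "lon"),
                      coords={"member": [0, 1], "year": [2000, 2001, 2002],
                              "month": np.arange(1, 13),
                              "lat": [0.0, 10.0], "lon": [0.0, 10.0]})
    got = annual_mean(da).values
    expect = np.empty((2, 3, 2, 2))
    for m in range(2):
        for y in range(3):
            expect[m, y] = vals[m, y].mean(axis=0)
    np.testing.assert_array_equal(got, expect)


def test_incomplete_year_error_names_the_year():
    n = 12 + 11  # 2000 complete, 2001 missing December
    vals = np.zeros((1, n, 1, 1))
    years = np.array([2000] * 12 + [2001] * 11)
    months = np.array(list(range(1, 13)) + list(range(1, 12)))
    da = xr.DataArray(vals, dims=("member", "time", "lat", "lon"),
                      coords={"member": [0], "lat": [0.0], "lon": [0.0],
                              "year": ("time", years), "month": ("time", months)})
    with pytest.raises(FormatError, match="2001"):
        annual_mean(da)


# -- NetCDF round trips ------------------------------------------------------


def test_netcdf_round_trip_is_bit_exact(tmp_path, stationary_cube):
    p = tmp_path / "cube.nc"
    save_cube(stationary_cube, p)
    back = load_cube(p)
    np.testing.assert_array_equal(back.values, stationary_cube.values)
    assert back.units == stationary_cube.units
    assert back.provenance == stationary_cube.provenance


def test_missing_member_dim_becomes_single_member(tmp_path):
    p = tmp_path / "nomem.nc"
    da = xr.DataArray(np.random.default_rng(0).normal(size=(3, 2, 2)),
                      dims=("year", "lat", "lon"),
                      coords={"year": [2000, 2001, 2002], "lat": [0.0, 10.0],
                              "lon": [0.0, 10.0]})
    da.to_dataset(name="mrsos").to_netcdf(p, engine="scipy")
    with pytest.warns(UserWarning, match="1-member"):
        cube = load_cube(p)
    assert cube.n_members == 1


def test_monthly_file_requires_explicit_annualize_flag(tmp_path):
    years = np.repeat([2000, 2001], 12)
    months = np.tile(np.arange(1, 13), 2)
    da = xr.DataArray(np.zeros((1, 24, 1, 1)), dims=("member", "time", "lat", "lon"),
                      coords={"member": [0], "lat": [0.0], "lon": [0.0],
                              "year": ("time", years), "month": ("time", months)})
    p = tmp_path / "monthly.nc"
    da.to_dataset(name="mrsos").to_netcdf(p, engine="scipy")
    with pytest.raises(FormatError, match="annualize"):
        load_cube(p)
    assert load_cube(p, annualize=True).values.shape == (1, 2, 1, 1)


# -- regions -----------------------------------------------------------------


def test_overlapping_regions_rejected(small_grid):
    with pytest.raises(GeometryError, match="overlap"):
        RegionSet.from_boxes(small_grid, {"A": (-60, 10, -180, 20), "B": (0, 60, 0, 180)})


def test_empty_region_rejected(small_grid):
    with pytest.raises(GeometryError, match="empty"):
        RegionSet.from_boxes(small_grid, {"A": (81, 89, 0, 1)})


def test_region_file_boxes_and_cells(tmp_path, small_grid):
    doc = """
regions:
  A: {box: [-60, 0, -180, 0]}
  B: {cells: [[4, 8], [5, 9]]}
"""
    p = tmp_path / "regions.yaml"
    p.write_text(doc)
    rs = RegionSet.from_file(small_grid, p)
    assert rs.masks["B"].sum() == 2
    assert not (rs.masks["A"] & rs.masks["B"]).any()
    assert rs.global_mask.sum() == rs.masks["A"].sum() + 2
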