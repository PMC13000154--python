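"""Drought classification, area series, and intensity."""

import numpy as np
import pytest

from shatterscan import (RegionSet, classify_drought, drought_area,
                         drought_intensity, fit_baseline)
from shatterscan.grid_io import GeometryError
from conftest import make_cube


def pooled_1_to_100_cube():
    """2 members x 50 years x 1 cell whose pooled sample is a permutation of
    {1, ..., 100}."""
    rng = np.random.default_rng(42)
    vals = rng.permutation(np.arange(1.0, 101.0)).reshape(2, 50, 1, 1)
    return make_cube(vals)


@pytest.mark.parametrize("p,expected", [(20.0, 20.8), (5.0, 5.95)])
def test_threshold_is_linear_interpolation_percentile(p, expected):
    # order-statistics oracle on {1..100}: q = 1 + p/100 * 99
    cube = pooled_1_to_100_cube()
    stats = fit_baseline(cube, ref_period=(1850, 1899), percentile=p)
    np.testing.assert_allclose(stats.threshold, expected)
    assert 1.0 <= stats.threshold[0, 0] <= 100.0


def test_constant_pool_is_degenerate():
    cube = make_cube(np.full((2, 50, 1, 1), 7.0))
    stats = fit_baseline(cube, (1850, 1899), 20.0)
    np.testing.assert_allclose(stats.threshold, 7.0)
    assert stats.degenerate.all()


@pytest.mark.parametrize("p", [0.0, 100.0, -5.0, 120.0])
def test_percentile_out_of_range_rejected(p):
    with pytest.raises(ValueError):
        fit_baseline(pooled_1_to_100_cube(), (1850, 1899), p)


def test_ref_period_outside_span_rejected():
    with pytest.raises(ValueError):
        fit_baseline(pooled_1_to_100_cube(), (1800, 1899), 20.0)


def test_threshold_boundary_is_strictly_below():
    cube = pooled_1_to_100_cube()
    stats = fit_baseline(cube, (1850, 1899), 20.0)
    at = cube.with_values(np.full_like(cube.values, stats.threshold[0, 0]))
    below = cube.with_values(np.full_like(cube.values, stats.threshold[0, 0] - 1e-9))
    assert not classify_drought(at, stats).values.any()
    assert classify_drought(below, stats).values.all()


def test_grid_mismatch_rejected(stationary_cube):
    stats = fit_baseline(pooled_1_to_100_cube(), (1850, 1899), 20.0)
    with pytest.raises(GeometryError):
        classify_drought(stationary_cube, stats)


def test_reference_sample_drought_frequency_matches_percentile(stationary_cube):
    """On the pooled baseline itself the drought frequency per cell is ~p%."""
    stats = fit_baseline(stationary_cube, (1850, 1899), 20.0)
    mask = classify_drought(stationary_cube.sel_years(1850, 1899), stats)
    freq = mask.values.mean(axis=(0, 1))  # per cell
    n = 12 * 50
    np.testing.assert_allclose(freq, 0.20, atol=2.0 / n + 1e-12)


def region_set_4cells():
    """One region of 4 equal-area cells plus one of 12, equatorial grid."""
    cube = make_cube(np.zeros((1, 1, 2, 8)))
    grid = cube.grid
    masks = {
        "A": np.zeros(grid.shape, bool),
        "B": np.zeros(grid.shape, bool),
    }
    masks["A"][:, :2] = True   # 4 cells
    masks["B"][:, 2:8] = True  # 12 cells
    return RegionSet(grid=grid, masks=masks, weights=np.ones(grid.shape))


def test_half_of_region_in_drought_is_fifty_percent():
    regions = region_set_4cells()
    mask = make_cube(np.zeros((1, 1, 2, 8))).data.astype(bool)
    m = mask.values
    m[0, 0, 0, 0] = m[0, 0, 1, 0] = True  # 2 of region A's 4 cells
    series = drought_area(mask.copy(data=m), regions, scope="A", denominator="regional")
    np.testing.assert_allclose(series.values.values, 50.0)


def test_quarter_weight_region_fully_in_drought_is_25_percent_global():
    regions = region_set_4cells()  # A holds 4 of 16 breadbasket cells
    mask = make_cube(np.zeros((1, 1, 2, 8))).data.astype(bool)
    m = mask.values
    m[0, 0, :, :2] = True  # all of A
    series = drought_area(mask.copy(data=m), regions, scope="A", denominator="global")
    np.testing.assert_allclose(series.values.values, 25.0)


def test_area_matches_per_cell_loop_oracle(stationary_cube, two_regions):
    stats = fit_baseline(stationary_cube, (1850, 1899), 20.0)
    mask = classify_drought(stationary_cube, stats)
    got = drought_area(mask, two_regions, scope="global", denominator="regional")
    m = mask.values
    w = two_regions.weights
    gm = two_regions.global_mask
    expect = np.empty(m.shape[:2])
    for i in range(m.shape[0]):
        for t in range(m.shape[1]):
            num = sum(w[a, b] for a, b in np.argwhere(gm) if m[i, t, a, b])
            expect[i, t] = 100.0 * num / w[gm].sum()
    np.testing.assert_allclose(got.values.values, expect, rtol=1e-12)


def test_regional_global_denominator_series_sum_to_global(stationary_cube, two_regions):
    stats = fit_baseline(stationary_cube, (1850, 1899), 20.0)
    mask = classify_drought(stationary_cube, stats)
    total = sum(
        drought_area(mask, two_regions, scope=r, denominator="global").values.values
        for r in two_regions.names)
    glob = drought_area(mask, two_regions, scope="global").values.values
    np.testing.assert_allclose(total, glob, atol=1e-9)


def test_unknown_scope_rejected(stationary_cube, two_regions):
    stats = fit_baseline(stationary_cube, (1850, 1899), 20.0)
    mask = classify_drought(stationary_cube, stats)
    with pytest.raises(KeyError):
        drought_area(mask, two_regions, scope="Atlantis")


def test_lower_percentile_never_increases_area(stationary_cube, two_regions):
    """Nested thresholds: area at p=5 <= area at p=20 for every member-year."""
    s20 = fit_baseline(stationary_cube, (1850, 1899), 20.0)
    s5 = fit_baseline(stationary_cube, (1850, 1899), 5.0)
    a20 = drought_area(classify_drought(stationary_cube, s20), two_regions).values.values
    a5 = drought_area(classify_drought(stationary_cube, s5), two_regions).values.values
    assert (a5 <= a20 + 1e-12).all()


# -- intensity ---------------------------------------------------------------


def test_uniform_minus_one_sigma_gives_intensity_minus_one(stationary_cube, two_regions):
    stats = fit_baseline(stationary_cube, (1850, 1899), 20.0)
    shifted = stationary_cube.with_values(
        np.broadcast_to(stats.mean - stats.sd, stationary_cube.values.shape))
    mask = classify_drought(shifted, stats)
    assert mask.values.all()  # -1 sigma is below the 20th-percentile threshold
    out = drought_intensity(shifted, mask, stats, two_regions)
    np.testing.assert_allclose(out.values, -1.0, rtol=1e-10)


def test_no_drought_cells_gives_missing_not_zero(stationary_cube, two_regions):
    stats = fit_baseline(stationary_cube, (1850, 1899), 20.0)
    wet = stationary_cube.with_values(np.full_like(stationary_cube.values, 1e6))
    mask = classify_drought(wet, stats)
    out = drought_intensity(wet, mask, stats, two_regions)
    assert np.isnan(out.values).all()


def test_intensity_matches_weighted_mean_oracle(stationary_cube, two_regions):
    stats = fit_baseline(stationary_cube, (1850, 1899), 20.0)
    mask = classify_drought(stationary_cube, stats)
    out = drought_intensity(stationary_cube, mask, stats, two_regions).values
    m = mask.values & two_regions.global_mask
    w = two_regions.weights
    z = (stationary_cube.values - stats.mean) / stats.sd
    i, t = 3, 17
    cells = np.argwhere(m[i, t])
    if cells.size:
        expect = (sum(w[a, b] * z[i, t, a, b] for a, b in cells)
                  / sum(w[a, b] for a, b in cells))
        np.testing.assert_allclose(out[i, t], expect, rtol=1e-10)


def test_zero_sigma_on_drought_cell_is_an_error(two_regions):
    vals = np.full((2, 250, 6, 12), 5.0)
    vals[:, 100:] = 0.0  # later years drop below the (constant) threshold? no:
    cube = make_cube(vals)
    # constant reference pool -> sd == 0 and threshold == 5; make one year lower
    cube2 = cube.with_values(np.where(
        np.arange(250)[None, :, None, None] == 200, 4.0, vals))
    stats = fit_baseline(cube2, (1850, 1899), 20.0)
    mask = classify_drought(cube2, stats)
    grid_regions = RegionSet(grid=cube.grid, masks={
        "A": np.ones(cube.grid.shape, bool)})
    with pytest.raises(FloatingPointError, match="lat_idx"):
        drought_intensity(cube2, mask, stats, grid_regions)
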