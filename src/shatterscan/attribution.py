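"""Leave-one-region-undetrended attribution of record-shattering risk.

To quantify how much one region's soil-moisture trend contributes to the
probability of at least one global record-shattering drought, that region's
series is kept unchanged while all other breadbasket cells are replaced by
their fully detrended (mean and SD stationarized) transform.  The region's
contribution is the difference between the global at-least-one probability of
this mixed experiment and that of the detrend-all experiment.  Contributions
of different regions are not additive — record statistics interact — so they
are reported individually, with a multi-model mean and inter-model range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detrend import detrend_both
from .drought import classify_drought, drought_area, fit_baseline
from .grid_io import RegionSet, SmileCube
from .records import RecordConfig, multimodel_summary, prob_at_least_one, record_events_table

__all__ = ["leave_one_region_undetrended", "regional_contributions"]


def leave_one_region_undetrended(
    cube: SmileCube,
    regions: RegionSet,
    keep: str,
    detrended: SmileCube | None = None,
    window: int = 31,
    ref_period: tuple[int, int] = (1850, 1899),
) -> SmileCube:
    """Detrend (both moments) every breadbasket cell except those of ``keep``.

    Cells of the kept region — and all cells outside any breadbasket, which
    never enter area computations — retain their original values bit-exactly.
    A precomputed ``detrend_both`` cube can be supplied to avoid recomputing
    it for each region.
    """
    if keep not in regions.masks:
        raise KeyError(f"unknown region {keep!r}; known: {regions.names}")
    if detrended is None:
        detrended = detrend_both(cube, window=window, ref_period=ref_period)
    replace_mask = regions.global_mask & ~regions.masks[keep]
    out = cube.values.copy()
    out[..., replace_mask] = detrended.values[..., replace_mask]
    return cube.with_values(out, note=f"leave-one-undetrended: kept {keep!r}")


def _global_prob(cube: SmileCube, regions: RegionSet, period: tuple[int, int],
                 config: RecordConfig, percentile: float,
                 ref_period: tuple[int, int]) -> float:
    baseline = fit_baseline(cube, ref_period, percentile)
    mask = classify_drought(cube, baseline)
    area = drought_area(mask, regions, scope="global", denominator="regional")
    events = record_events_table(area, config)
    return prob_at_least_one(events, area.n_members, period)


def regional_contributions(
    cubes: dict[str, SmileCube],
    regions: RegionSet,
    period: tuple[int, int] = (2026, 2099),
    config: RecordConfig = RecordConfig(),
    percentile: float = 20.0,
    window: int = 31,
    ref_period: tuple[int, int] = (1850, 1899),
) -> pd.DataFrame:
    """Per-region trend contributions to P(>=1 global record-shattering event).

    For each model: the original-data probability, the detrend-all
    probability, and for each region the leave-one-undetrended probability
    and its contribution (difference to detrend-all).  Thresholds are refit
    on each experiment's own preindustrial pool.  Rows with model
    "__summary__" hold the multi-model mean and inter-model range.
    """
    rows = []
    for model, cube in cubes.items():
        det = detrend_both(cube, window=window, ref_period=ref_period)
        p_orig = _global_prob(cube, regions, period, config, percentile, ref_period)
        p_all = _global_prob(det, regions, period, config, percentile, ref_period)
        rows.append({"model": model, "region": "__original__", "probability": p_orig,
                     "contribution": np.nan})
        rows.append({"model": model, "region": "__detrend_all__", "probability": p_all,
                     "contribution": np.nan})
        for name in regions.names:
            mixed = leave_one_region_undetrended(cube, regions, keep=name, detrended=det)
            p = _global_prob(mixed, regions, period, config, percentile, ref_period)
            rows.append({"model": model, "region": name, "probability": p,
                         "contribution": p - p_all})
    df = pd.DataFrame(rows)
    summaries = []
    for region, grp in df.groupby("region", sort=False):
        for col in ("probability", "contribution"):
            vals = grp[col].dropna()
            if len(vals) == 0:
                continue
            s = multimodel_summary(vals)
            summaries.append({"model": "__summary__", "region": region, "quantity": col,
                              "mean": s["mean"], "range_low": s["range"][0],
                              "range_high": s["range"][1]})
    df["quantity"] = "per_model"
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
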