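"""Realism diagnostics against a modern reference window.

Record-shattering probabilities cannot be evaluated against the short
observational record directly, so simulated ensembles are judged on the two
quantities that drive those probabilities: the linear trend and the
interannual variability of annual drought area over a recent window.
Droughts here are defined against a 1980-2009 pooled baseline (for a
single-realization reference dataset the "pool" is that one realization) and
areas are computed for 1980-2024; no detrending is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drought import AreaSeries, classify_drought, drought_area, fit_baseline
from .grid_io import RegionSet, SmileCube

__all__ = [
    "EvalWindowConfig",
    "eval_drought_area",
    "linear_trend",
    "interannual_sd",
    "within_sigma",
    "evaluation_table",
]


@dataclass(frozen=True)
class EvalWindowConfig:
    ref_period: tuple[int, int] = (1980, 2009)
    eval_period: tuple[int, int] = (1980, 2024)
    percentile: float = 20.0

    def __post_init__(self) -> None:
        if not (self.ref_period[0] >= self.eval_period[0] and self.ref_period[1] <= self.eval_period[1]):
            raise ValueError("reference period must lie within the evaluation period")


def eval_drought_area(cube: SmileCube, regions: RegionSet,
                      cfg: EvalWindowConfig = EvalWindowConfig()) -> dict[str, AreaSeries]:
    """Drought-area series for the global scope and each region over the
    evaluation period, with thresholds fit on the modern reference pool."""
    years = cube.years
    if cfg.eval_period[0] < years.min() or cfg.eval_period[1] > years.max():
        raise ValueError(f"cube years {years.min()}-{years.max()} do not cover "
                         f"evaluation period {cfg.eval_period}")
    baseline = fit_baseline(cube, cfg.ref_period, cfg.percentile)
    mask = classify_drought(cube.sel_years(*cfg.eval_period), baseline)
    out = {}
    for scope in ["global"] + regions.names:
        out[scope] = drought_area(mask, regions, scope=scope, denominator="regional")
    return out


def linear_trend(area: AreaSeries) -> pd.DataFrame:
    """OLS trend of drought area on year, in % per decade, per member.

    Returns a frame (member, slope) plus a "__summary__" row with the member
    mean and the member SD (sample, n-1) — the model-level summary used to
    compare against reference datasets.
    """
    years = area.years.astype(float)
    if years.size < 3:
        raise ValueError("need at least 3 years for a trend")
    if np.ptp(years) == 0:
        raise ValueError("constant time axis")
    slopes = []
    for m in range(area.n_members):
        slope = np.polyfit(years, area.member(m), 1)[0] * 10.0
        slopes.append({"member": m, "slope_pct_per_decade": float(slope)})
    df = pd.DataFrame(slopes)
    s = df["slope_pct_per_decade"]
    summary = pd.DataFrame([{"member": "__summary__",
                             "slope_pct_per_decade": float(s.mean()),
                             "member_sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0}])
    return pd.concat([df, summary], ignore_index=True)


def interannual_sd(area: AreaSeries) -> pd.DataFrame:
    """Sample SD (n-1) of annual drought area per member, with a summary row."""
    if area.years.size < 2:
        raise ValueError("need at least 2 years")
    rows = [{"member": m, "sd": float(np.std(area.member(m), ddof=1))}
            for m in range(area.n_members)]
    df = pd.DataFrame(rows)
    summary = pd.DataFrame([{"member": "__summary__", "sd": float(df["sd"].mean())}])
    return pd.concat([df, summary], ignore_index=True)


def within_sigma(model_value: float, ref_value: float, ref_sigma: float) -> bool:
    """Agreement predicate: model summary falls inside the reference ±σ band."""
    return abs(model_value - ref_value) <= ref_sigma


def evaluation_table(cube: SmileCube, regions: RegionSet,
                     cfg: EvalWindowConfig = EvalWindowConfig(),
                     dataset: str = "model") -> pd.DataFrame:
    """One-row-per-scope diagnostics table: trend (%/decade, member mean ± SD)
    and interannual σ of drought area."""
    areas = eval_drought_area(cube, regions, cfg)
    rows = []
    for scope, area in areas.items():
        tr = linear_trend(area)
        sd = interannual_sd(area)
        tr_sum = tr[tr["member"] == "__summary__"].iloc[0]
        rows.append({
            "dataset": dataset,
            "scope": scope,
            "trend_pct_per_decade": tr_sum["slope_pct_per_decade"],
            "trend_member_sd": tr_sum.get("member_sd", 0.0),
            "interannual_sd": sd[sd["member"] == "__summary__"]["sd"].iloc[0],
        })
    return pd.DataFrame(rows)
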