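"""Record-breaking and record-shattering event detection and probabilities.

A record-shattering drought is a year whose drought area exceeds the running
maximum of its own ensemble member by at least a fixed margin (default 5
percentage points of the scope's area); with margin zero the detector reduces
to ordinary record-breaking (strict exceedance by any amount).  The running
maximum is initialized at the first tracked year, which is therefore never
itself an event, and updates whenever a year exceeds it — event or not.

Probabilities are counting-based: the annual probability divides event counts
inside a 31-year moving window by window-years times members; period
probabilities are the fraction of members with at least one in-period event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .drought import AreaSeries

__all__ = [
    "RecordConfig",
    "find_record_events",
    "record_events_table",
    "annual_probability",
    "prob_at_least_one",
    "multimodel_summary",
]


@dataclass(frozen=True)
class RecordConfig:
    """Margin in percentage points of the scope's area (0 = record-breaking);
    records are tracked from ``tracking_start`` (default: the first year)."""

    margin: float = 5.0
    tracking_start: int | None = None

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


def find_record_events(
    values: np.ndarray,
    years: np.ndarray,
    config: RecordConfig = RecordConfig(),
) -> pd.DataFrame:
    """Scan one member's annual series for record(-shattering) events.

    A year is an event when its value reaches the running maximum plus the
    margin (``>=`` for a positive margin, strict ``>`` for margin zero).
    Returns a frame with columns (year, value, exceedance).
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years)
    if values.size == 0:
        raise ValueError("empty series")
    if values.shape != years.shape:
        raise ValueError("values and years must have the same length")
    start = config.tracking_start if config.tracking_start is not None else years[0]
    keep = years >= start
    v, y = values[keep], years[keep]
    if v.size < 2:
        raise ValueError("need at least 2 tracked years to define a previous record")
    rows = []
    running = v[0]
    for i in range(1, v.size):
        if config.margin > 0:
            hit = v[i] >= running + config.margin
        else:
            hit = v[i] > running
        if hit:
            rows.append((int(y[i]), float(v[i]), float(v[i] - running)))
        if v[i] > running:
            running = v[i]
    return pd.DataFrame(rows, columns=["year", "value", "exceedance"])


def record_events_table(area: AreaSeries, config: RecordConfig = RecordConfig()) -> pd.DataFrame:
    """Event table over all members of an area series: columns
    (member, year, value, exceedance, type)."""
    frames = []
    years = area.years
    etype = "shattering" if config.margin > 0 else "breaking"
    for m in range(area.n_members):
        ev = find_record_events(area.member(m), years, config)
        if len(ev):
            ev.insert(0, "member", m)
            frames.append(ev)
    if not frames:
        out = pd.DataFrame({"member": pd.Series(dtype=int), "year": pd.Series(dtype=int),
                            "value": pd.Series(dtype=float), "exceedance": pd.Series(dtype=float)})
    else:
        out = pd.concat(frames, ignore_index=True)
    out["type"] = etype
    return out


def annual_probability(
    events: pd.DataFrame,
    years: np.ndarray,
    n_members: int,
    window: int = 31,
    full_windows_only: bool = True,
) -> pd.Series:
    """Moving-window annual event probability.

    p(center) = (events in [center - h, center + h] across all members) /
    (window years x members).  With ``full_windows_only`` (default) only
    centers whose +-h window lies entirely inside the data span are reported;
    otherwise edge windows are truncated and divided by their actual
    year-count times members.
    """
    years = np.asarray(years)
    if n_members < 1:
        raise ValueError("need at least one member")
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if window > years.size:
        raise ValueError(f"window {window} larger than series span {years.size}")
    h = window // 2
    ev_years = events["year"].to_numpy() if len(events) else np.array([], dtype=int)
    centers, probs = [], []
    for c in years:
        lo, hi = c - h, c + h
        if full_windows_only and (lo < years[0] or hi > years[-1]):
            continue
        n_years = int(np.clip(hi, None, years[-1]) - np.clip(lo, years[0], None)) + 1
        count = int(((ev_years >= lo) & (ev_years <= hi)).sum())
        centers.append(int(c))
        probs.append(count / (n_years * n_members))
    return pd.Series(probs, index=pd.Index(centers, name="year"), name="probability")


def prob_at_least_one(events: pd.DataFrame, n_members: int, period: tuple[int, int]) -> float:
    """Fraction of members with >= 1 event year inside the inclusive period."""
    if n_members < 1:
        raise ValueError("empty member set")
    if len(events) == 0:
        return 0.0
    sel = events[(events["year"] >= period[0]) & (events["year"] <= period[1])]
    return sel["member"].nunique() / n_members


def multimodel_summary(per_model: Sequence[float] | Iterable[float]) -> dict:
    """Unweighted multi-model mean plus the inter-model (min, max) range,
    the standard uncertainty band for ensembles of ensemble means."""
    vals = np.asarray(list(per_model), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one model")
    return {"mean": float(vals.mean()), "range": (float(vals.min()), float(vals.max()))}
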