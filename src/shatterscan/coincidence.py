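"""Coincidence of global record-shattering droughts with regional droughts.

Three complementary views of how global record-shattering events relate to
what individual breadbaskets experience in the same ensemble member:

1. *Simultaneous record-shattering*: how many regions are under a regional
   record-shattering drought in the global event year — a partition into
   "0 regions", single-region categories, "2 regions" … "6 regions".
2. *Simultaneous moderately extreme droughts*: the same partition, but a
   region counts when its drought area exceeds the 80th percentile of its
   own trailing 31-year (Y-30..Y) distribution — drought that is unusual
   relative to the ongoing climatology without shattering any record.
3. *±15-year association*: the fraction of global events with a regional
   record-shattering event within 15 years before or after, which checks
   that view 2 is not an artifact of regional records simply never occurring
   near the global event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .drought import AreaSeries
from .records import multimodel_summary

__all__ = [
    "ModerateDroughtRule",
    "is_moderately_extreme",
    "moderate_flags",
    "events_to_flags",
    "classify_global_events",
    "multimodel_coincidence",
    "windowed_association",
]


@dataclass(frozen=True)
class ModerateDroughtRule:
    """Trailing-window percentile rule: year Y is moderately extreme when its
    regional drought area strictly exceeds the given percentile of the
    {Y-window+1 .. Y} distribution of the same member (Y included in its own
    reference pool)."""

    window: int = 31
    percentile: float = 80.0


def is_moderately_extreme(
    area: AreaSeries, member: int, year: int, rule: ModerateDroughtRule = ModerateDroughtRule()
) -> bool:
    """Evaluate the trailing-percentile rule for one member-year."""
    years = area.years
    first = int(years[0])
    if year - (rule.window - 1) < first:
        raise ValueError(
            f"insufficient history: year {year} needs {rule.window} trailing years, "
            f"series starts {first}")
    vals = area.member(member)
    i = int(np.searchsorted(years, year))
    if i >= years.size or years[i] != year:
        raise ValueError(f"year {year} not in series")
    pool = vals[i - (rule.window - 1): i + 1]
    return bool(vals[i] > np.percentile(pool, rule.percentile))


def moderate_flags(area: AreaSeries, rule: ModerateDroughtRule = ModerateDroughtRule()) -> pd.DataFrame:
    """Boolean flags (member x year) for all years with full trailing windows."""
    years = area.years
    w = rule.window
    eval_years = years[w - 1:]
    out = np.zeros((area.n_members, eval_years.size), dtype=bool)
    for m in range(area.n_members):
        vals = area.member(m)
        for k, _y in enumerate(eval_years):
            pool = vals[k: k + w]
            out[m, k] = vals[k + w - 1] > np.percentile(pool, rule.percentile)
    return pd.DataFrame(out, index=pd.Index(range(area.n_members), name="member"),
                        columns=pd.Index(eval_years, name="year"))


def events_to_flags(events: pd.DataFrame, n_members: int, years: np.ndarray) -> pd.DataFrame:
    """Convert an event table (member, year, ...) into a (member x year)
    boolean frame usable by :func:`classify_global_events`."""
    years = np.asarray(years)
    out = np.zeros((n_members, years.size), dtype=bool)
    if len(events):
        col = {int(y): k for k, y in enumerate(years)}
        for _, ev in events.iterrows():
            out[int(ev["member"]), col[int(ev["year"])]] = True
    return pd.DataFrame(out, index=pd.Index(range(n_members), name="member"),
                        columns=pd.Index(years, name="year"))


def _flag_lookup(flags: pd.DataFrame, member: int, year: int) -> bool:
    if year not in flags.columns:
        return False
    return bool(flags.loc[member, year])


def classify_global_events(
    global_events: pd.DataFrame,
    regional_flags: Mapping[str, pd.DataFrame],
    period: tuple[int, int] = (2000, 2099),
    highlight: Sequence[str] | None = None,
) -> pd.Series:
    """Partition global events by how many regions are simultaneously flagged.

    ``regional_flags`` maps region name to a (member x year) boolean frame —
    either regional record-shattering event indicators or moderately extreme
    flags.  Single-region events are sub-split into one category per
    ``highlight`` region plus "Rest only" for the remaining regions.  Returns
    percentages summing to 100 over mutually exclusive categories; raises if
    no global event falls in the period (an empty partition has no
    fractions).
    """
    names = list(regional_flags)
    if highlight is None:
        highlight = names[:3]
    sel = global_events[(global_events["year"] >= period[0]) & (global_events["year"] <= period[1])]
    categories = (["0 regions"] + [f"{r} only" for r in highlight] + ["Rest only"]
                  + [f"{k} regions" for k in range(2, len(names) + 1)])
    counts = pd.Series(0, index=pd.Index(categories, name="category"), dtype=float)
    if len(sel) == 0:
        raise ValueError(f"no global record-shattering events in period {period}")
    for _, ev in sel.iterrows():
        m, y = int(ev["member"]), int(ev["year"])
        flagged = [r for r in names if _flag_lookup(regional_flags[r], m, y)]
        k = len(flagged)
        if k == 0:
            counts["0 regions"] += 1
        elif k == 1:
            r = flagged[0]
            counts[f"{r} only" if r in highlight else "Rest only"] += 1
        else:
            counts[f"{k} regions"] += 1
    return 100.0 * counts / counts.sum()


def multimodel_coincidence(per_model: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Multi-model mean of per-model coincidence fractions, with the
    inter-model range per category."""
    df = pd.DataFrame(per_model)
    return pd.DataFrame({
        "mean": df.mean(axis=1),
        "range_low": df.min(axis=1),
        "range_high": df.max(axis=1),
    })


def windowed_association(
    global_events: pd.DataFrame,
    regional_events: Mapping[str, pd.DataFrame],
    half_window: int = 15,
    period: tuple[int, int] = (2000, 2085),
) -> pd.Series:
    """Fraction of global events with a same-member regional record-shattering
    event within ``half_window`` years before or after, per region.

    Global events are restricted to ``period`` so the full ±window fits the
    study span.  Returns one fraction per region (NaN if no global events).
    """
    sel = global_events[(global_events["year"] >= period[0]) & (global_events["year"] <= period[1])]
    out = {}
    for name, rev in regional_events.items():
        if len(sel) == 0:
            out[name] = np.nan
            continue
        hits = 0
        for _, ev in sel.iterrows():
            m, y = int(ev["member"]), int(ev["year"])
            ry = rev.loc[rev["member"] == m, "year"].to_numpy()
            if np.any(np.abs(ry - y) <= half_window):
                hits += 1
        out[name] = hits / len(sel)
    return pd.Series(out, name="fraction").rename_axis("region")
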