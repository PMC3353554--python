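"""Weekly airborne-pollen aggregation and comparison with the flowering maps.

Daily Hirst-trap concentrations (grains/m³) are summed into fixed 7-day
windows — the weekly pollen index.  The peak week locates the maximum of the
pollen curve; joining per-date full-flowering map fractions with the index of
the containing week supports the qualitative question of which areas feed
the pollen curve.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PollenSeries
from .mapping import FloweringMask

__all__ = [
    "WeeklyPollenIndex",
    "weekly_pollen_index",
    "peak_week",
    "flowering_pollen_table",
    "default_week_anchor",
]


@dataclass
class WeeklyPollenIndex:
    """Pollen index (grains·day/m³) per consecutive 7-day window."""

    week_starts: list[_dt.date]
    indices: np.ndarray
    complete: np.ndarray  # True where all 7 days were observed

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=float)
        self.complete = np.asarray(self.complete, dtype=bool)
        if not (len(self.week_starts) == len(self.indices) == len(self.complete)):
            raise ValueError("weekly fields must align")
        for a, b in zip(self.week_starts, self.week_starts[1:]):
            if (b - a).days != 7:
                raise ValueError("weeks must be consecutive 7-day windows")

    def __len__(self) -> int:
        return len(self.week_starts)

    def week_of(self, date: _dt.date) -> int | None:
        """Index of the week containing ``date``, or None if outside the span."""
        if not self.week_starts:
            return None
        k = (date - self.week_starts[0]).days // 7
        return k if 0 <= k < len(self) else None


def default_week_anchor(first_date: _dt.date) -> _dt.date:
    """First Monday on or before the first observation."""
    return first_date - _dt.timedelta(days=first_date.weekday())


def weekly_pollen_index(
    series: PollenSeries, week_anchor: _dt.date | None = None
) -> WeeklyPollenIndex:
    """Sum daily counts into consecutive 7-day windows from ``week_anchor``.

    Missing days contribute 0; weeks with fewer than 7 observed days are
    flagged incomplete.
    """
    if len(series) == 0:
        raise ValueError("empty pollen series")
    anchor = week_anchor or default_week_anchor(series.dates[0])
    if anchor > series.dates[0]:
        raise ValueError("week_anchor must be on or before the first observation")
    n_weeks = (series.dates[-1] - anchor).days // 7 + 1
    idx = np.zeros(n_weeks)
    days_seen = np.zeros(n_weeks, dtype=int)
    for d, c in zip(series.dates, series.counts):
        k = (d - anchor).days // 7
        idx[k] += c
        days_seen[k] += 1
    return WeeklyPollenIndex(
        week_starts=[anchor + _dt.timedelta(days=7 * k) for k in range(n_weeks)],
        indices=idx,
        complete=days_seen == 7,
    )


def peak_week(weekly: WeeklyPollenIndex) -> tuple[_dt.date, float, bool]:
    """Week with the maximum pollen index.

    Ties are broken by the earliest week; returns ``(week_start, index, tied)``.
    """
    if len(weekly) == 0:
        raise ValueError("no weeks")
    k = int(np.argmax(weekly.indices))
    tied = bool(np.sum(weekly.indices == weekly.indices[k]) > 1)
    return weekly.week_starts[k], float(weekly.indices[k]), tied


def flowering_pollen_table(
    masks: dict[_dt.date, FloweringMask], weekly: WeeklyPollenIndex
) -> pd.DataFrame:
    """Join per-date full-flowering area fractions with their week's pollen index.

    Dates outside the weekly span are kept with a flag and a missing index.
    """
    rows = []
    for date in sorted(masks):
        k = weekly.week_of(date)
        rows.append(
            {
                "date": date.isoformat(),
                "area_fraction": masks[date].area_fraction,
                "week_start": weekly.week_starts[k].isoformat() if k is not None else "",
                "pollen_index": float(weekly.indices[k]) if k is not None else np.nan,
                "in_span": k is not None,
            }
        )
    return pd.DataFrame(
        rows, columns=["date", "area_fraction", "week_start", "pollen_index", "in_span"]
    )
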