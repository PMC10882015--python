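"""Annual heatwave indices.

Reduces the per-cell event list to nine annual indices per percentile
definition:

========  ==============================================================
AHW       land area (km^2) hosting >= 1 daytime heatwave in the year
DHW       maximum daytime heatwave duration (days)
THW       maximum daily Tmax over daytime heatwave days (degC)
CTHW      cumulative exceedance sum(Tmax - threshold) over heatwave days
HWI       heatwave index: sum over events of the event cell's area as a
          fraction of total land area (affected fraction x event count)
AHWN      area with joint day-night heatwaves, as % of total land area
DHWN      maximum day-night heatwave duration (days)
THWN      maximum Tmax over day-night heatwave days (degC)
CTHWN     cumulative exceedance over day-night heatwave days (degC)
========  ==============================================================

Events are per-cell: a heat episode covering k cells counts as k cell
events, which matters for HWI.  THW/CTHW aggregation rules (max peak,
summed exceedance) are config-selectable because one-line index glosses
admit both readings; the defaults are scale-free across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import HeatwaveEvent
from .grid import GridDefinition

INDEX_COLUMNS = ["AHW", "DHW", "THW", "CTHW", "HWI", "AHWN", "DHWN", "THWN", "CTHWN"]


@dataclass(frozen=True)
class AnnualHeatwaveSummary:
    year: int
    percentile: float
    AHW: float  # km^2
    DHW: int  # days
    THW: float  # degC
    CTHW: float  # degC (cumulative exceedance)
    HWI: float  # dimensionless
    AHWN: float  # % of total land area
    DHWN: int
    THWN: float
    CTHWN: float
    n_events_day: int
    n_events_night: int
    AHW_cells: int  # affected-cell count (alternative AHW scale)
    AHWN_km2: float
    zero_event_flag: bool

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _mode_stats(events: list[HeatwaveEvent], areas: np.ndarray, thw_stat: str):
    cells = {e.cell for e in events}
    area = float(sum(areas[c] for c in cells))
    if not events:
        return cells, area, 0, 0.0, 0.0
    dur = max(e.duration for e in events)
    peaks = [e.peak_tmax for e in events]
    thw = float(max(peaks) if thw_stat == "max" else np.mean(peaks))
    cthw = float(sum(e.cumulative_exceedance for e in events))
    return cells, area, dur, thw, cthw


def annual_summary(
    events: list[HeatwaveEvent],
    grid: GridDefinition,
    year: int,
    percentile: float,
    thw_stat: str = "max",
) -> AnnualHeatwaveSummary:
    """The nine indices for one (year, percentile).

    ``events`` may contain other years/percentiles; they are filtered out.
    ``thw_stat`` selects the THW/THWN aggregation over events ("max", the
    default, or "mean").  With no events every index is 0 and
    ``zero_event_flag`` is set.
    """
    if thw_stat not in ("max", "mean"):
        raise ValueError(f"unknown thw_stat {thw_stat!r}")
    areas = grid.cell_areas_km2()
    total = grid.total_land_area_km2()
    day = [
        e
        for e in events
        if e.year == year and e.percentile == percentile and e.mode == "day"
    ]
    night = [
        e
        for e in events
        if e.year == year and e.percentile == percentile and e.mode == "day_night"
    ]
    dcells, darea, ddur, dthw, dcthw = _mode_stats(day, areas, thw_stat)
    ncells, narea, ndur, nthw, ncthw = _mode_stats(night, areas, thw_stat)
    hwi = float(sum(areas[e.cell] for e in day)) / total if total > 0 else 0.0
    return AnnualHeatwaveSummary(
        year=year,
        percentile=percentile,
        AHW=darea,
        DHW=ddur,
        THW=dthw,
        CTHW=dcthw,
        HWI=hwi,
        AHWN=100.0 * narea / total if total > 0 else 0.0,
        DHWN=ndur,
        THWN=nthw,
        CTHWN=ncthw,
        n_events_day=len(day),
        n_events_night=len(night),
        AHW_cells=len(dcells),
        AHWN_km2=narea,
        zero_event_flag=not day and not night,
    )


def index_timeseries(
    events: list[HeatwaveEvent],
    grid: GridDefinition,
    years,
    percentile: float,
    thw_stat: str = "max",
) -> pd.DataFrame:
    """One row per year (zero years included) for one percentile, ordered by
    year and ready for trend analysis."""
    years = list(years)
    rows = [
        annual_summary(events, grid, y, percentile, thw_stat).as_dict() for y in years
    ]
    return pd.DataFrame(rows)
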