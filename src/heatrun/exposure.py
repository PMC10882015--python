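"""Population exposure to heatwaves.

Overlays annual heatwave-affected cell masks with gridded population to
produce per-year affected-population maps and time series.  A person is
counted once per year regardless of how many events touched their cell; a
person-days variant (duration-weighted) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import HeatwaveEvent
from .grid import GridDefinition, PopulationGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExposureSeries:
    years: tuple[int, ...]
    percentile: float
    mode: str
    affected_population: np.ndarray  # persons, per year
    affected_population_map: np.ndarray  # persons, (year, lat, lon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "percentile": self.percentile,
                "affected_population": self.affected_population,
            }
        )


def affected_mask(
    events: list[HeatwaveEvent],
    grid: GridDefinition,
    year: int,
    percentile: float,
    mode: str = "day",
) -> np.ndarray:
    """Boolean (n_lat, n_lon) mask: True where the cell hosts >= 1 event of
    the given year/percentile/mode."""
    mask = np.zeros(grid.shape, dtype=bool)
    for e in events:
        if e.year == year and e.percentile == percentile and e.mode == mode:
            mask[e.cell] = True
    return mask


def affected_population(mask: np.ndarray, pop: PopulationGrid) -> float:
    """Population (persons) in masked cells; nodata cells contribute 0."""
    if mask.shape != pop.grid.shape:
        raise ValueError("mask shape does not match the population grid")
    return float(np.nansum(np.where(mask, pop.counts, 0.0)))


def exposure_series(
    events: list[HeatwaveEvent],
    pops: dict[int, PopulationGrid],
    percentile: float,
    years,
    mode: str = "day",
    nearest_year: bool = False,
    person_days: bool = False,
) -> ExposureSeries:
    """Affected population per year for one percentile/mode.

    ``pops`` maps year -> population aggregated to the analysis grid.  By
    default the exact year must be present; with ``nearest_year`` the
    closest available year is substituted (and logged).  ``person_days``
    weights each cell's population by the total heatwave days there.
    """
    years = tuple(int(y) for y in years)
    if not pops:
        raise ValueError("no population data supplied")
    avail = sorted(pops)
    series = np.zeros(len(years))
    some_grid = pops[avail[0]].grid
    maps = np.zeros((len(years),) + some_grid.shape)
    for k, year in enumerate(years):
        if year in pops:
            pop = pops[year]
        elif nearest_year:
            near = min(avail, key=lambda a: abs(a - year))
            logger.info("population for %d missing; using %d", year, near)
            pop = pops[near]
        else:
            raise ValueError(f"no population raster for year {year}")
        mask = affected_mask(events, pop.grid, year, percentile, mode)
        if person_days:
            days = np.zeros(pop.grid.shape)
            for e in events:
                if e.year == year and e.percentile == percentile and e.mode == mode:
                    days[e.cell] += e.duration
            cellvals = np.where(mask, np.nan_to_num(pop.counts) * days, 0.0)
        else:
            cellvals = np.where(mask, np.nan_to_num(pop.counts), 0.0)
        maps[k] = cellvals
        series[k] = cellvals.sum()
    return ExposureSeries(years, percentile, mode, series, maps)
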