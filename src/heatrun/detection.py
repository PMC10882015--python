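"""Percentile thresholds, heatwave-run extraction and Malaysian alert levels.

A heatwave at a grid cell is a maximal run of >= 3 consecutive days with
daily Tmax strictly above the cell's reference-period percentile threshold
(day mode), or with both Tmax and Tmin above their respective thresholds on
the same days (day-night mode).  Thresholds are empirical quantiles (95th,
97.5th, 99th) of all daily values in a fixed reference window, 1961-1990 by
default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import GridDailyTemperature, GridDefinition

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (95.0, 97.5, 99.0)
MIN_RUN_DAYS = 3


@dataclass(frozen=True)
class ThresholdField:
    """Per-cell Tmax/Tmin percentile thresholds over a reference period.

    ``tmax_thresholds[p]`` and ``tmin_thresholds[p]`` are (n_lat, n_lon)
    arrays keyed by percentile; NaN marks cells with insufficient reference
    data, which are excluded downstream.
    """

    grid: GridDefinition
    percentiles: tuple[float, ...]
    tmax_thresholds: dict[float, np.ndarray]
    tmin_thresholds: dict[float, np.ndarray]
    reference_period: tuple[int, int]

    def __post_init__(self) -> None:
        ps = sorted(self.percentiles)
        for lo, hi in zip(ps, ps[1:]):
            for d in (self.tmax_thresholds, self.tmin_thresholds):
                a, b = d[lo], d[hi]
                ok = np.isfinite(a) & np.isfinite(b)
                if np.any(a[ok] > b[ok] + 1e-9):
                    raise ValueError("thresholds must be non-decreasing in percentile")


@dataclass(frozen=True)
class HeatwaveEvent:
    """One maximal exceedance run at one grid cell."""

    cell: tuple[int, int]
    start_index: int
    year: int
    start_date: str
    end_date: str
    duration: int
    peak_tmax: float
    cumulative_exceedance: float
    mode: str  # "day" | "day_night"
    percentile: float


def compute_thresholds(
    temp: GridDailyTemperature,
    reference_period: tuple[int, int] = (1961, 1990),
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    pool: str = "pooled",
    doy_half_window: int = 7,
    max_missing_fraction: float = 0.1,
) -> ThresholdField:
    """Empirical per-cell quantiles of daily Tmax and Tmin in the reference
    window.

    ``pool="pooled"`` (default) uses every reference-period day; with
    ``pool="doy_window"`` each calendar day's threshold pools days within
    ``doy_half_window`` days (circularly) and the per-cell threshold is
    returned as the pooled-window mean across the calendar -- exposed as a
    sensitivity switch, since the domain's seasonal range is weak.  Linear
    interpolation between order statistics.  Cells with more than
    ``max_missing_fraction`` of their reference days missing get NaN
    thresholds.
    """
    y0, y1 = reference_period
    sel = (temp.time.year >= y0) & (temp.time.year <= y1)
    if not sel.any():
        raise ValueError(f"reference period {reference_period} outside the data period")
    tmax_thresholds: dict[float, np.ndarray] = {}
    tmin_thresholds: dict[float, np.ndarray] = {}
    for arr, out in ((temp.tmax, tmax_thresholds), (temp.tmin, tmin_thresholds)):
        ref = arr[sel]
        missing_frac = np.mean(~np.isfinite(ref), axis=0)
        bad = missing_frac > max_missing_fraction
        if pool == "pooled":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                for p in percentiles:
                    q = np.nanpercentile(ref, p, axis=0)
                    q[bad] = np.nan
                    out[p] = q
        elif pool == "doy_window":
            doy = temp.time.doy[sel]
            n_doy = 365 if temp.time.calendar == "noleap" else 366
            for p in percentiles:
                per_doy = np.full((n_doy,) + ref.shape[1:], np.nan)
                for d in range(1, n_doy + 1):
                    dist = np.minimum(np.abs(doy - d), n_doy - np.abs(doy - d))
                    window = ref[dist <= doy_half_window]
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        per_doy[d - 1] = np.nanpercentile(window, p, axis=0)
                q = per_doy.mean(axis=0)
                q[bad] = np.nan
                out[p] = q
        else:
            raise ValueError(f"unknown pool mode {pool!r}")
        if bad.any():
            logger.info("thresholds undefined for %d cells (missing data)", int(bad.sum()))
    return ThresholdField(
        temp.grid, tuple(percentiles), tmax_thresholds, tmin_thresholds, reference_period
    )


def detect_runs(exceed: np.ndarray, min_len: int = MIN_RUN_DAYS) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= ``min_len`` as (start, length).

    Missing days must already be encoded as False (a run breaker).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    x = np.asarray(exceed, dtype=bool).astype(np.int8)
    if x.size == 0:
        return []
    edges = np.diff(np.concatenate([[0], x, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends) if e - s >= min_len]


def extract_events(
    temp: GridDailyTemperature,
    thresholds: ThresholdField,
    percentile: float,
    mode: str = "day",
    min_len: int = MIN_RUN_DAYS,
) -> list[HeatwaveEvent]:
    """Extract heatwave events at one percentile for all land cells.

    Exceedance is strict (> threshold); day-night mode requires Tmax and
    Tmin to exceed their thresholds on the same day.  Missing days break
    runs.  Events are attributed to the year containing their start day.
    Cells with undefined thresholds are skipped (counted in the log).
    """
    if mode not in ("day", "day_night"):
        raise ValueError(f"unknown mode {mode!r}")
    if percentile not in thresholds.tmax_thresholds:
        raise ValueError(f"percentile {percentile} not present in thresholds")
    thr_max = thresholds.tmax_thresholds[percentile]
    thr_min = thresholds.tmin_thresholds[percentile]
    dates = temp.time.date_strings()
    events: list[HeatwaveEvent] = []
    skipped = 0
    nlat, nlon = temp.grid.shape
    for i in range(nlat):
        for j in range(nlon):
            if not temp.grid.land_mask[i, j]:
                continue
            tmx = thr_max[i, j]
            tmn = thr_min[i, j]
            if not np.isfinite(tmx) or (mode == "day_night" and not np.isfinite(tmn)):
                skipped += 1
                continue
            tx = temp.tmax[:, i, j]
            mask = np.isfinite(tx) & (tx > tmx)
            if mode == "day_night":
                tn = temp.tmin[:, i, j]
                mask &= np.isfinite(tn) & (tn > tmn)
            for start, length in detect_runs(mask, min_len):
                seg = tx[start : start + length]
                events.append(
                    HeatwaveEvent(
                        cell=(i, j),
                        start_index=start,
                        year=int(temp.time.year[start]),
                        start_date=dates[start],
                        end_date=dates[start + length - 1],
                        duration=length,
                        peak_tmax=float(seg.max()),
                        cumulative_exceedance=float((seg - tmx).sum()),
                        mode=mode,
                        percentile=percentile,
                    )
                )
    if skipped:
        logger.info("skipped %d cells with undefined thresholds", skipped)
    return events


def classify_malaysian_level(tmax_window) -> int:
    """Malaysian heatwave alert level for a 3-day Tmax window (degC).

    With m the minimum over the 3 days: level 1 (Alert) for m in [35, 37),
    level 2 (heatwave announcement) for m in [37, 40], level 3 (state of
    emergency) for m > 40, else 0.  The nominal band edges overlap at 37;
    the boundary day belongs to the higher band.  A missing value yields
    level 0 with a warning.
    """
    window = np.asarray(tmax_window, dtype=float)
    if window.shape != (3,):
        raise ValueError("exactly 3 consecutive daily Tmax values are required")
    if not np.all(np.isfinite(window)):
        warnings.warn("missing value in 3-day window; level 0 returned", stacklevel=2)
        return 0
    m = window.min()
    if m > 40.0:
        return 3
    if m >= 37.0:
        return 2
    if m >= 35.0:
        return 1
    return 0
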