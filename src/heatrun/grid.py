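"""Gridded data containers and I/O for the heatwave analysis.

Holds the regular lat-lon grid definition, the daily Tmax/Tmin cube, and
population rasters, together with readers/writers for the standard text and
NetCDF formats and the area/aggregation arithmetic the indices need.

Conventions: coordinates are cell centers, latitudes ascending, indices
0-based, time steps are whole days.  Missing values are NaN throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0

_NOLEAP_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_NOLEAP_MONTH_STARTS = np.concatenate([[0], np.cumsum(_NOLEAP_MONTH_LENGTHS)])


class GridFormatError(ValueError):
    """Raised when an on-disk grid file does not match the expected layout."""


@dataclass(frozen=True)
class TimeAxis:
    """Gap-free daily time axis.

    ``calendar`` is ``"noleap"`` (365-day, used by the synthetic generator) or
    ``"standard"`` (true proleptic-Gregorian calendar, used for real data).
    """

    year: np.ndarray
    month: np.ndarray
    day: np.ndarray
    calendar: str = "noleap"

    def __post_init__(self) -> None:
        if self.calendar not in ("noleap", "standard"):
            raise ValueError(f"unknown calendar {self.calendar!r}")
        for name in ("year", "month", "day"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        if not (len(self.year) == len(self.month) == len(self.day)):
            raise ValueError("year/month/day must have equal length")

    def __len__(self) -> int:
        return len(self.year)

    @classmethod
    def noleap_range(cls, start_year: int, n_years: int) -> "TimeAxis":
        """Daily axis over ``n_years`` full 365-day years starting Jan 1."""
        month = np.empty(365, dtype=int)
        day = np.empty(365, dtype=int)
        for m in range(12):
            sl = slice(_NOLEAP_MONTH_STARTS[m], _NOLEAP_MONTH_STARTS[m + 1])
            month[sl] = m + 1
            day[sl] = np.arange(1, _NOLEAP_MONTH_LENGTHS[m] + 1)
        years = np.repeat(np.arange(start_year, start_year + n_years), 365)
        return cls(years, np.tile(month, n_years), np.tile(day, n_years), "noleap")

    @classmethod
    def from_datetimes(cls, dates) -> "TimeAxis":
        idx = pd.DatetimeIndex(dates)
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError("time axis must be gap-free at daily step")
        return cls(idx.year.values, idx.month.values, idx.day.values, "standard")

    @property
    def doy(self) -> np.ndarray:
        """Day of year (1-based; noleap numbering for the noleap calendar)."""
        if self.calendar == "noleap":
            return _NOLEAP_MONTH_STARTS[self.month - 1] + self.day
        return pd.DatetimeIndex(self.to_datetimes()).dayofyear.values

    def to_datetimes(self) -> pd.DatetimeIndex:
        if self.calendar != "standard":
            raise ValueError("noleap axis has no datetime representation")
        return pd.to_datetime(
            {"year": self.year, "month": self.month, "day": self.day}
        ).pipe(pd.DatetimeIndex)

    def index_of(self, year: int, month: int, day: int) -> int:
        hit = np.flatnonzero((self.year == year) & (self.month == month) & (self.day == day))
        if hit.size == 0:
            raise KeyError(f"date {year:04d}-{month:02d}-{day:02d} not on time axis")
        return int(hit[0])

    def date_strings(self) -> np.ndarray:
        return np.array(
            [f"{y:04d}-{m:02d}-{d:02d}" for y, m, d in zip(self.year, self.month, self.day)]
        )


def _check_regular(centers: np.ndarray, what: str, tol: float = 1e-6) -> float:
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 1 or centers.size == 0:
        raise ValueError(f"{what} centers must be a non-empty 1-D array")
    if centers.size == 1:
        return np.nan
    steps = np.diff(centers)
    if np.any(steps <= 0):
        raise ValueError(f"{what} centers must be strictly ascending")
    if np.ptp(steps) > tol:
        raise ValueError(f"{what} spacing irregular beyond {tol} degrees")
    return float(steps.mean())


@dataclass(frozen=True)
class GridDefinition:
    """Regular lat-lon grid of cell centers with a boolean land mask."""

    lat: np.ndarray
    lon: np.ndarray
    cell_size: float
    land_mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
        object.__setattr__(self, "lon", np.asarray(self.lon, dtype=float))
        object.__setattr__(self, "land_mask", np.asarray(self.land_mask, dtype=bool))
        for centers, what in ((self.lat, "lat"), (self.lon, "lon")):
            step = _check_regular(centers, what)
            if np.isfinite(step) and abs(step - self.cell_size) > 1e-6:
                raise ValueError(f"{what} spacing {step} != cell_size {self.cell_size}")
        if self.land_mask.shape != self.shape:
            raise ValueError(
                f"land_mask shape {self.land_mask.shape} != grid shape {self.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    def cell_areas_km2(self) -> np.ndarray:
        """Per-cell spherical areas, shape (n_lat, n_lon)."""
        band = np.array([cell_area_km2(phi, self.cell_size) for phi in self.lat])
        return np.repeat(band[:, None], self.lon.size, axis=1)

    def total_land_area_km2(self) -> float:
        return float(self.cell_areas_km2()[self.land_mask].sum())


def cell_area_km2(lat_center: float, cell_size: float) -> float:
    """Spherical-Earth area (km^2) of a cell_size x cell_size cell.

    Band area R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)) with
    R = 6371 km; latitude bounds are clipped to the poles.
    """
    if abs(lat_center) > 90:
        raise ValueError("|lat| must be <= 90")
    half = cell_size / 2.0
    top = np.radians(min(lat_center + half, 90.0))
    bot = np.radians(max(lat_center - half, -90.0))
    dlam = np.radians(cell_size)
    return EARTH_RADIUS_KM**2 * dlam * (np.sin(top) - np.sin(bot))


@dataclass
class GridDailyTemperature:
    """Daily Tmax/Tmin cube (degC) on a regular grid; NaN marks missing."""

    grid: GridDefinition
    time: TimeAxis
    tmax: np.ndarray
    tmin: np.ndarray

    def __post_init__(self) -> None:
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.tmin = np.asarray(self.tmin, dtype=float)
        expected = (len(self.time),) + self.grid.shape
        for name, arr in (("tmax", self.tmax), ("tmin", self.tmin)):
            if arr.shape != expected:
                raise ValueError(f"{name} shape {arr.shape} != {expected}")
        both = np.isfinite(self.tmax) & np.isfinite(self.tmin)
        if np.any(self.tmax[both] < self.tmin[both] - 1e-9):
            raise ValueError("tmax < tmin encountered")

    def copy(self) -> "GridDailyTemperature":
        return GridDailyTemperature(
            self.grid, self.time, self.tmax.copy(), self.tmin.copy()
        )

    def to_netcdf(self, path: str | Path) -> None:
        """Write a CF-style NetCDF3 file (time/lat/lon; tmax, tmin in degC)."""
        t0_year = int(self.time.year[0])
        units = f"days since {t0_year:04d}-01-01"
        if self.time.calendar == "noleap":
            tvals = (
                (self.time.year - t0_year) * 365
                + _NOLEAP_MONTH_STARTS[self.time.month - 1]
                + self.time.day
                - 1
            ).astype(float)
        else:
            dt = self.time.to_datetimes()
            tvals = (dt - pd.Timestamp(f"{t0_year:04d}-01-01")).days.astype(float)
        ds = xr.Dataset(
            {
                "tmax": (("time", "lat", "lon"), self.tmax),
                "tmin": (("time", "lat", "lon"), self.tmin),
                "land_mask": (("lat", "lon"), self.grid.land_mask.astype(np.int8)),
            },
            coords={"time": tvals, "lat": self.grid.lat, "lon": self.grid.lon},
        )
        ds["tmax"].attrs["units"] = "degC"
        ds["tmin"].attrs["units"] = "degC"
        ds["time"].attrs["units"] = units
        ds["time"].attrs["calendar"] = (
            "365_day" if self.time.calendar == "noleap" else "standard"
        )
        ds["lat"].attrs["units"] = "degrees_north"
        ds["lon"].attrs["units"] = "degrees_east"
        ds.to_netcdf(path, engine="scipy")


def _decode_time(tvals: np.ndarray, units: str, calendar: str) -> TimeAxis:
    if not units.startswith("days since"):
        raise GridFormatError(f"unsupported time units {units!r}")
    origin = units.removeprefix("days since").strip().split(" ")[0]
    oy, om, od = (int(x) for x in origin.split("-"))
    days = np.round(np.asarray(tvals, dtype=float)).astype(int)
    if calendar in ("365_day", "noleap"):
        if (om, od) != (1, 1):
            days = days + int(_NOLEAP_MONTH_STARTS[om - 1] + od - 1)
        year = oy + days // 365
        doy = days % 365
        month = np.searchsorted(_NOLEAP_MONTH_STARTS, doy, side="right")
        day = doy - _NOLEAP_MONTH_STARTS[month - 1] + 1
        return TimeAxis(year, month, day, "noleap")
    dates = pd.Timestamp(f"{oy:04d}-{om:02d}-{od:02d}") + pd.to_timedelta(days, unit="D")
    return TimeAxis.from_datetimes(dates)


def read_temperature_netcdf(
    path: str | Path,
    var_names: tuple[str, str] = ("tmax", "tmin"),
    unit_hint: str | None = None,
    land_mask: np.ndarray | None = None,
) -> GridDailyTemperature:
    """Read a daily Tmax/Tmin cube from a CF-style NetCDF file.

    Latitudes are normalized to ascending (reanalysis files often ship them
    descending), and values with a kelvin ``units`` attribute (or
    ``unit_hint="K"``) are converted to degC.  ``land_mask`` overrides any
    mask variable stored in the file; all-land is assumed when neither exists.
    """
    ds = xr.open_dataset(path, engine="scipy", decode_times=False)
    for v in var_names:
        if v not in ds:
            raise GridFormatError(
                f"variable {v!r} not found in {path}; present: {list(ds.data_vars)}"
            )
    for dim in ("time", "lat", "lon"):
        if dim not in ds.dims:
            raise GridFormatError(f"dimension {dim!r} missing from {path}")

    lat = ds["lat"].values.astype(float)
    flip = lat.size > 1 and lat[0] > lat[-1]
    if flip:
        ds = ds.isel(lat=slice(None, None, -1))
        lat = ds["lat"].values.astype(float)

    fields = {}
    units_seen = set()
    for v in var_names:
        arr = ds[v].transpose("time", "lat", "lon").values.astype(float)
        units = unit_hint or ds[v].attrs.get("units", "degC")
        units_seen.add(units.lower())
        if units.lower() in ("k", "kelvin"):
            arr = arr - 273.15
        elif units.lower() not in ("degc", "celsius", "c", "degrees_celsius", "°c"):
            raise GridFormatError(f"unrecognized temperature units {units!r} on {v}")
        fields[v] = arr
    if len(units_seen) > 1:
        raise GridFormatError(f"mixed temperature units across variables: {units_seen}")

    time = _decode_time(
        ds["time"].values,
        ds["time"].attrs.get("units", ""),
        ds["time"].attrs.get("calendar", "standard"),
    )
    lon = ds["lon"].values.astype(float)
    if lat.size > 1:
        step = np.diff(lat).mean()
    elif lon.size > 1:
        step = np.diff(lon).mean()
    else:
        step = 1.0  # degenerate single-cell file: spacing unrecoverable
    if land_mask is None:
        if "land_mask" in ds:
            land_mask = ds["land_mask"].values.astype(bool)
        else:
            land_mask = np.ones((lat.size, lon.size), dtype=bool)
    grid = GridDefinition(lat, lon, float(step), land_mask)
    return GridDailyTemperature(grid, time, fields[var_names[0]], fields[var_names[1]])


@dataclass
class PopulationGrid:
    """Gridded population counts for one year; NaN marks nodata cells."""

    grid: GridDefinition
    year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts shape mismatch with grid")
        if np.any(self.counts[np.isfinite(self.counts)] < 0):
            raise ValueError("population counts must be non-negative")

    def total(self) -> float:
        return float(np.nansum(self.counts))


def _interval_overlap_matrix(
    fine_centers: np.ndarray, fine_size: float, coarse_centers: np.ndarray, coarse_size: float
) -> np.ndarray:
    """(n_coarse, n_fine) matrix of the fraction of each fine interval
    covered by each coarse interval."""
    flo = fine_centers - fine_size / 2
    fhi = fine_centers + fine_size / 2
    clo = coarse_centers - coarse_size / 2
    chi = coarse_centers + coarse_size / 2
    lo = np.maximum(clo[:, None], flo[None, :])
    hi = np.minimum(chi[:, None], fhi[None, :])
    return np.clip(hi - lo, 0.0, None) / fine_size


def aggregate_population_to_grid(
    fine: PopulationGrid, target: GridDefinition
) -> PopulationGrid:
    """Area-weighted aggregation of a fine population raster onto ``target``.

    Each target cell receives sum over fine cells of count x fractional-area
    overlap; nodata fine cells are skipped (contribute nothing).  When the
    fine grid nests exactly this reduces to a block sum.
    """
    wlat = _interval_overlap_matrix(
        fine.grid.lat, fine.grid.cell_size, target.lat, target.cell_size
    )
    wlon = _interval_overlap_matrix(
        fine.grid.lon, fine.grid.cell_size, target.lon, target.cell_size
    )
    if wlat.sum() == 0 or wlon.sum() == 0:
        raise ValueError("fine grid extent is disjoint from the target grid")
    counts = np.nan_to_num(fine.counts, nan=0.0)
    coarse = wlat @ counts @ wlon.T
    return PopulationGrid(target, fine.year, coarse)


def write_ascii_grid(pop: PopulationGrid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (rows north to south)."""
    g = pop.grid
    vals = np.where(np.isfinite(pop.counts), pop.counts, nodata)[::-1]
    with open(path, "w") as fh:
        fh.write(f"ncols {g.lon.size}\n")
        fh.write(f"nrows {g.lat.size}\n")
        fh.write(f"xllcorner {g.lon[0] - g.cell_size / 2:.10g}\n")
        fh.write(f"yllcorner {g.lat[0] - g.cell_size / 2:.10g}\n")
        fh.write(f"cellsize {g.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_population_raster(path: str | Path, year: int) -> PopulationGrid:
    """Read an ESRI ASCII population grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= header.keys():
        raise GridFormatError(
            f"ASCII grid missing header keys: {sorted(required - header.keys())}"
        )
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = np.vstack(rows)
    if data.shape != (nrows, ncols):
        raise GridFormatError(f"data shape {data.shape} != header ({nrows}, {ncols})")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    cs = header["cellsize"]
    lon = header["xllcorner"] + cs * (np.arange(ncols) + 0.5)
    lat = header["yllcorner"] + cs * (np.arange(nrows) + 0.5)
    grid = GridDefinition(lat, lon, cs, np.ones((nrows, ncols), dtype=bool))
    return PopulationGrid(grid, year, data[::-1])  # file rows are north->south


def export_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a table with full double precision and a locale-independent
    decimal point; round-trips losslessly through ``pandas.read_csv``."""
    frame.to_csv(path, index=False, float_format="%.17g")
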