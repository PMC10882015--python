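"""Synthetic climate and population generator.

Emulates the statistical structure the downstream analysis assumes for a
humid-tropical domain like Peninsular Malaysia: a weak seasonal cycle
(monthly-mean Tmax between 28.1 degC in December and 30.8 degC in April,
Tmin between 21.8 and 23.3 degC), serially correlated daily anomalies
(iid, AR(1) or fractional Gaussian noise with a Hurst exponent), a secular
warming trend, injectable multi-day heat events with known footprints, and
clustered population rasters at finer resolution than the temperature grid.

All outputs are bit-reproducible from the config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import (
    GridDailyTemperature,
    GridDefinition,
    PopulationGrid,
    TimeAxis,
    _NOLEAP_MONTH_LENGTHS,
    _NOLEAP_MONTH_STARTS,
)

# Monthly-mean cycles (Jan..Dec, degC).  Anchors: Tmax lowest in December
# (28.1) and highest in April (30.8); Tmin lowest in January (21.8) and
# highest in May (23.3).  Intermediate months are a smooth fill between the
# anchors.
DEFAULT_TMAX_CYCLE = (28.6, 29.6, 30.5, 30.8, 30.6, 30.2, 29.9, 29.9, 29.7, 29.5, 28.8, 28.1)
DEFAULT_TMIN_CYCLE = (21.8, 22.0, 22.4, 23.0, 23.3, 23.0, 22.7, 22.7, 22.6, 22.5, 22.3, 22.0)


class SyntheticConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass(frozen=True)
class SyntheticClimateConfig:
    n_years: int = 40
    start_year: int = 1961
    grid_shape: tuple[int, int] = (4, 4)
    cell_size_deg: float = 0.25
    lat0: float = 2.0
    lon0: float = 101.0
    tmax_annual_cycle: tuple[float, ...] = DEFAULT_TMAX_CYCLE
    tmin_annual_cycle: tuple[float, ...] = DEFAULT_TMIN_CYCLE
    noise_model: str = "ar1"  # iid | ar1 | fgn
    ar1_phi: float | None = 0.6
    hurst_H: float | None = None
    noise_sd: float = 0.5
    trend_per_decade: float = 0.18
    diurnal_offset_sd: float = 0.2
    lat_gradient_c_per_deg: float = 0.0
    seasonal_interp: str = "linear"  # linear | step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1 or min(self.grid_shape) < 1:
            raise SyntheticConfigError("n_years and grid_shape must be positive")
        if len(self.tmax_annual_cycle) != 12 or len(self.tmin_annual_cycle) != 12:
            raise SyntheticConfigError("annual cycles need 12 monthly means")
        if not all(
            a > b for a, b in zip(self.tmax_annual_cycle, self.tmin_annual_cycle)
        ):
            raise SyntheticConfigError("tmax monthly means must exceed tmin means")
        if self.noise_model not in ("iid", "ar1", "fgn"):
            raise SyntheticConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_model == "ar1":
            if self.ar1_phi is None or not -1 < self.ar1_phi < 1:
                raise SyntheticConfigError("ar1 noise requires ar1_phi in (-1, 1)")
        if self.noise_model == "fgn":
            if self.hurst_H is None or not 0.5 < self.hurst_H < 1:
                raise SyntheticConfigError("fgn noise requires hurst_H in (0.5, 1)")
        if self.noise_sd < 0 or self.diurnal_offset_sd < 0:
            raise SyntheticConfigError("noise standard deviations must be >= 0")
        if self.seasonal_interp not in ("linear", "step"):
            raise SyntheticConfigError(f"unknown seasonal_interp {self.seasonal_interp!r}")


@dataclass(frozen=True)
class InjectedEventSpec:
    """Ground-truth heat event: amplitude added to Tmax (and optionally Tmin)
    at the given cells for ``duration`` consecutive days."""

    cell_indices: tuple[tuple[int, int], ...]
    start_date: str  # "YYYY-MM-DD"
    duration: int
    amplitude: float
    tmin_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("duration must be >= 1")


@dataclass(frozen=True)
class SyntheticPopulationConfig:
    fine_factor: int = 4
    n_clusters: int = 3
    total_population: int = 1_000_000
    na_fraction: float = 0.0
    cluster_scale_cells: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fine_factor < 1:
            raise ValueError("fine_factor must be >= 1")
        if not 0 <= self.na_fraction < 1:
            raise ValueError("na_fraction must be in [0, 1)")


def fgn_autocovariance(n: int, H: float) -> np.ndarray:
    """Autocovariance (unit variance) of fractional Gaussian noise at lags
    0..n-1: rho_l = 0.5(|l+1|^2H - 2|l|^2H + |l-1|^2H)."""
    lags = np.arange(n, dtype=float)
    return 0.5 * (
        np.abs(lags + 1) ** (2 * H) - 2 * np.abs(lags) ** (2 * H) + np.abs(lags - 1) ** (2 * H)
    )


def generate_fgn(
    n: int, H: float, sd: float = 1.0, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Exact fractional Gaussian noise of length ``n``.

    Uses Davies-Harte circulant embedding of the fGn autocovariance; if the
    embedding is not non-negative definite (it is for fGn in theory, but
    rounding can intrude at extreme H), falls back to a Cholesky factor of
    the n x n correlation matrix.  The method used is recorded on the
    returned array as ``.method`` via a small ndarray subclass-free trick:
    the function attribute ``generate_fgn.last_method`` holds it.
    """
    if not 0 < H < 1:
        raise ValueError("H must be in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gamma = fgn_autocovariance(n, H)
    # circulant embedding of size 2n-2
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(circ).real
    if np.min(eig) >= -1e-10:
        eig = np.clip(eig, 0.0, None)
        m = circ.size
        # rfft of a real symmetric circulant: synthesize with Hermitian noise
        k = eig.size
        z = rng.standard_normal(k) + 1j * rng.standard_normal(k)
        z[0] = z[0].real * np.sqrt(2)
        if m % 2 == 0:
            z[-1] = z[-1].real * np.sqrt(2)
        w = np.sqrt(eig / (2 * m)) * z
        x = np.fft.irfft(w, n=m) * m
        out = x[:n]
        generate_fgn.last_method = "circulant"
    else:  # pragma: no cover - theoretical safeguard
        L = np.linalg.cholesky(_toeplitz(gamma))
        out = L @ rng.standard_normal(n)
        generate_fgn.last_method = "cholesky"
    return sd * out


generate_fgn.last_method = "none"


def _toeplitz(c: np.ndarray) -> np.ndarray:
    idx = np.abs(np.subtract.outer(np.arange(c.size), np.arange(c.size)))
    return c[idx]


def _daily_cycle(monthly: np.ndarray, interp: str) -> np.ndarray:
    """Expand 12 monthly means to a 365-day cycle.

    ``step`` repeats each monthly mean across its month; ``linear``
    interpolates periodically between month midpoints.
    """
    monthly = np.asarray(monthly, dtype=float)
    if interp == "step":
        return np.repeat(monthly, _NOLEAP_MONTH_LENGTHS)
    mid = _NOLEAP_MONTH_STARTS[:-1] + (_NOLEAP_MONTH_LENGTHS - 1) / 2.0
    xp = np.concatenate([[mid[-1] - 365], mid, [mid[0] + 365]])
    fp = np.concatenate([[monthly[-1]], monthly, [monthly[0]]])
    return np.interp(np.arange(365, dtype=float), xp, fp)


def _anomaly_series(cfg: SyntheticClimateConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_sd == 0:
        return np.zeros(n)
    if cfg.noise_model == "iid":
        return cfg.noise_sd * rng.standard_normal(n)
    if cfg.noise_model == "ar1":
        phi = cfg.ar1_phi
        eps = rng.standard_normal(n) * cfg.noise_sd * np.sqrt(1 - phi**2)
        out = np.empty(n)
        out[0] = rng.standard_normal() * cfg.noise_sd
        for t in range(1, n):
            out[t] = phi * out[t - 1] + eps[t]
        return out
    return generate_fgn(n, cfg.hurst_H, cfg.noise_sd, rng)


def generate_daily_temperature(cfg: SyntheticClimateConfig) -> GridDailyTemperature:
    """Simulate the daily Tmax/Tmin cube on a 365-day calendar.

    Tmax = seasonal cycle + latitude gradient + trend + anomaly; Tmin uses
    its own cycle, shares the daily anomaly, adds an independent diurnal
    offset, and is clipped so Tmax >= Tmin everywhere.
    """
    nlat, nlon = cfg.grid_shape
    lat = cfg.lat0 + cfg.cell_size_deg * np.arange(nlat)
    lon = cfg.lon0 + cfg.cell_size_deg * np.arange(nlon)
    grid = GridDefinition(lat, lon, cfg.cell_size_deg, np.ones((nlat, nlon), dtype=bool))
    time = TimeAxis.noleap_range(cfg.start_year, cfg.n_years)
    n = len(time)

    tmax_cyc = np.tile(_daily_cycle(cfg.tmax_annual_cycle, cfg.seasonal_interp), cfg.n_years)
    tmin_cyc = np.tile(_daily_cycle(cfg.tmin_annual_cycle, cfg.seasonal_interp), cfg.n_years)
    trend = cfg.trend_per_decade * np.arange(n) / 3650.0
    lat_term = cfg.lat_gradient_c_per_deg * (lat - lat.mean())

    rng = np.random.default_rng(cfg.seed)
    tmax = np.empty((n, nlat, nlon))
    tmin = np.empty((n, nlat, nlon))
    for i in range(nlat):
        for j in range(nlon):
            anom = _anomaly_series(cfg, n, rng)
            offset = (
                cfg.diurnal_offset_sd * rng.standard_normal(n)
                if cfg.diurnal_offset_sd > 0
                else 0.0
            )
            tx = tmax_cyc + lat_term[i] + trend + anom
            tn = tmin_cyc + lat_term[i] + trend + anom + offset
            tmax[:, i, j] = tx
            tmin[:, i, j] = np.minimum(tn, tx)
    return GridDailyTemperature(grid, time, tmax, tmin)


def inject_heatwaves(
    temp: GridDailyTemperature, events: list[InjectedEventSpec]
) -> tuple[GridDailyTemperature, pd.DataFrame]:
    """Add the specified heat events to a copy of ``temp``.

    Returns the modified cube plus a ground-truth ledger with one row per
    (cell, event): cell_lat_idx, cell_lon_idx, start_date, duration,
    amplitude.  Events outside the grid or the simulated period are rejected
    with the offending index named.
    """
    out = temp.copy()
    rows = []
    nlat, nlon = temp.grid.shape
    for k, ev in enumerate(events):
        y, m, d = (int(x) for x in ev.start_date.split("-"))
        try:
            t0 = temp.time.index_of(y, m, d)
        except KeyError as exc:
            raise ValueError(f"event {k}: {exc.args[0]}") from None
        if t0 + ev.duration > len(temp.time):
            raise ValueError(f"event {k} extends past the simulated period")
        for (i, j) in ev.cell_indices:
            if not (0 <= i < nlat and 0 <= j < nlon):
                raise ValueError(f"event {k}: cell ({i}, {j}) outside grid {nlat}x{nlon}")
            sl = slice(t0, t0 + ev.duration)
            out.tmax[sl, i, j] += ev.amplitude
            out.tmin[sl, i, j] += ev.tmin_amplitude
            out.tmin[sl, i, j] = np.minimum(out.tmin[sl, i, j], out.tmax[sl, i, j])
            rows.append(
                {
                    "cell_lat_idx": i,
                    "cell_lon_idx": j,
                    "start_date": ev.start_date,
                    "duration": ev.duration,
                    "amplitude": ev.amplitude,
                }
            )
    ledger = pd.DataFrame(
        rows, columns=["cell_lat_idx", "cell_lon_idx", "start_date", "duration", "amplitude"]
    )
    return out, ledger


def generate_population(
    cfg: SyntheticPopulationConfig, grid: GridDefinition, year: int = 2000
) -> PopulationGrid:
    """Clustered population raster at ``fine_factor`` times the resolution of
    ``grid``; non-NA counts sum exactly to ``total_population``."""
    f = cfg.fine_factor
    nlat, nlon = grid.shape
    cs = grid.cell_size / f
    lat = grid.lat[0] - grid.cell_size / 2 + cs * (np.arange(nlat * f) + 0.5)
    lon = grid.lon[0] - grid.cell_size / 2 + cs * (np.arange(nlon * f) + 0.5)
    fine_grid = GridDefinition(lat, lon, cs, np.ones((nlat * f, nlon * f), dtype=bool))

    rng = np.random.default_rng(cfg.seed)
    ii, jj = np.meshgrid(np.arange(nlat * f), np.arange(nlon * f), indexing="ij")
    weight = np.full(fine_grid.shape, 0.05)
    scale = cfg.cluster_scale_cells * f / 4.0 + 1e-9
    for _ in range(cfg.n_clusters):
        ci = rng.uniform(0, nlat * f)
        cj = rng.uniform(0, nlon * f)
        weight += np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * scale**2))

    na = rng.random(fine_grid.shape) < cfg.na_fraction
    weight[na] = 0.0
    p = weight.ravel() / weight.sum()
    counts = rng.multinomial(cfg.total_population, p).reshape(fine_grid.shape).astype(float)
    counts[na] = np.nan
    return PopulationGrid(fine_grid, year, counts)
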