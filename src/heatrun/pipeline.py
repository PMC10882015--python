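"""Config-driven orchestration of the full heatwave analysis.

The configuration is a single YAML/JSON-style mapping validated against a
strict schema (unknown keys rejected); a resolved copy is written alongside
the outputs together with a checksum manifest, so every run is auditable
and bit-reproducible from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import detection, exposure, indices, synthetic, trend
from .grid import (
    GridDailyTemperature,
    PopulationGrid,
    aggregate_population_to_grid,
    export_csv,
    read_population_raster,
    read_temperature_netcdf,
    write_ascii_grid,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class DataError(RuntimeError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ClimateSection(_Strict):
    n_years: int = 40
    start_year: int = 1961
    grid_shape: tuple[int, int] = (4, 4)
    cell_size_deg: float = 0.25
    lat0: float = 2.0
    lon0: float = 101.0
    tmax_annual_cycle: tuple[float, ...] = synthetic.DEFAULT_TMAX_CYCLE
    tmin_annual_cycle: tuple[float, ...] = synthetic.DEFAULT_TMIN_CYCLE
    noise_model: Literal["iid", "ar1", "fgn"] = "ar1"
    ar1_phi: float | None = 0.6
    hurst_H: float | None = None
    noise_sd: float = 0.5
    trend_per_decade: float = 0.18
    diurnal_offset_sd: float = 0.2
    lat_gradient_c_per_deg: float = 0.0
    seasonal_interp: Literal["linear", "step"] = "linear"


class EventSection(_Strict):
    cells: list[tuple[int, int]]
    start_date: str
    duration: int
    amplitude: float
    tmin_amplitude: float = 0.0


class PopulationSection(_Strict):
    fine_factor: int = 4
    n_clusters: int = 3
    total_population: int = 1_000_000
    na_fraction: float = 0.0
    years: list[int] = Field(default_factory=lambda: [2000])


class SyntheticSection(_Strict):
    climate: ClimateSection = Field(default_factory=ClimateSection)
    population: PopulationSection = Field(default_factory=PopulationSection)
    events: list[EventSection] = Field(default_factory=list)


class InputSection(_Strict):
    temperature_nc: str
    population_rasters: dict[int, str] = Field(default_factory=dict)
    var_names: tuple[str, str] = ("tmax", "tmin")
    unit_hint: str | None = None


class PipelineConfig(_Strict):
    seed: int = 0
    output_dir: str = "heatrun_out"
    synthetic: SyntheticSection | None = None
    inputs: InputSection | None = None
    reference_period: tuple[int, int] = (1961, 1990)
    percentiles: tuple[float, ...] = (95.0, 97.5, 99.0)
    min_run_days: int = 3
    modes: tuple[str, ...] = ("day", "day_night")
    threshold_pool: Literal["pooled", "doy_window"] = "pooled"
    max_missing_fraction: float = 0.1
    thw_stat: Literal["max", "mean"] = "max"
    bias_correction: bool = True
    ltp: Literal["auto", "always", "never"] = "auto"
    exposure_mode: Literal["day", "day_night"] = "day"
    exposure_years: list[int] | None = None
    nearest_population_year: bool = False
    report_map_years: list[int] | None = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be given")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
        return PipelineConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: Path, paths: list[Path]) -> Path:
    manifest = {p.name: _sha256(p) for p in sorted(paths)}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    return mpath


def _dump_config(cfg: PipelineConfig, outdir: Path) -> Path:
    path = outdir / "config.resolved.yaml"
    path.write_text(yaml.safe_dump(json.loads(cfg.model_dump_json()), sort_keys=True))
    return path


def simulate(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Write synthetic temperature, population and ground-truth event files."""
    if cfg.synthetic is None:
        raise ConfigError("'synthetic' section required for simulate")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clim = synthetic.SyntheticClimateConfig(
        **cfg.synthetic.climate.model_dump(), seed=cfg.seed
    )
    temp = synthetic.generate_daily_temperature(clim)
    specs = [
        synthetic.InjectedEventSpec(
            tuple(map(tuple, ev.cells)), ev.start_date, ev.duration,
            ev.amplitude, ev.tmin_amplitude,
        )
        for ev in cfg.synthetic.events
    ]
    temp, ledger = synthetic.inject_heatwaves(temp, specs)
    paths: dict[str, Path] = {}
    nc = outdir / "temperature.nc"
    temp.to_netcdf(nc)
    paths["temperature"] = nc
    led = outdir / "ground_truth_events.csv"
    export_csv(ledger, led)
    paths["ground_truth"] = led
    popcfg = cfg.synthetic.population
    for k, year in enumerate(popcfg.years):
        pop = synthetic.generate_population(
            synthetic.SyntheticPopulationConfig(
                fine_factor=popcfg.fine_factor,
                n_clusters=popcfg.n_clusters,
                total_population=popcfg.total_population,
                na_fraction=popcfg.na_fraction,
                seed=cfg.seed + 1000 + k,
            ),
            temp.grid,
            year,
        )
        p = outdir / f"population_{year}.asc"
        write_ascii_grid(pop, p)
        paths[f"population_{year}"] = p
    cfgpath = _dump_config(cfg, outdir)
    write_manifest(outdir, list(paths.values()) + [cfgpath])
    logger.info("simulate: wrote %d files to %s", len(paths), outdir)
    return paths


def _load_temperature(cfg: PipelineConfig, workdir: Path) -> GridDailyTemperature:
    if cfg.inputs is not None:
        try:
            return read_temperature_netcdf(
                cfg.inputs.temperature_nc, cfg.inputs.var_names, cfg.inputs.unit_hint
            )
        except Exception as exc:
            raise DataError(f"temperature stage: {exc}") from exc
    nc = workdir / "temperature.nc"
    if not nc.exists():
        raise DataError(f"temperature stage: {nc} missing (run simulate first)")
    return read_temperature_netcdf(nc)


def _load_populations(cfg: PipelineConfig, workdir: Path, grid) -> dict[int, PopulationGrid]:
    pops: dict[int, PopulationGrid] = {}
    if cfg.inputs is not None:
        items = [(y, Path(p)) for y, p in cfg.inputs.population_rasters.items()]
    else:
        items = [
            (y, workdir / f"population_{y}.asc") for y in cfg.synthetic.population.years
        ]
    for year, path in items:
        if not path.exists():
            raise DataError(f"exposure stage: population raster {path} missing")
        fine = read_population_raster(path, year)
        pops[year] = aggregate_population_to_grid(fine, grid)
    return pops


def _write_masks(temp, events, percentile, mode, years, outdir: Path) -> Path:
    arr = np.stack(
        [
            exposure.affected_mask(events, temp.grid, y, percentile, mode)
            for y in years
        ]
    ).astype(np.int8)
    ds = xr.Dataset(
        {"affected": (("year", "lat", "lon"), arr)},
        coords={"year": list(years), "lat": temp.grid.lat, "lon": temp.grid.lon},
    )
    path = outdir / f"affected_mask_p{percentile:g}_{mode}.nc"
    ds.to_netcdf(path, engine="scipy")
    return path


def run(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Full analysis: thresholds -> events -> indices -> trends -> exposure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    temp = _load_temperature(cfg, outdir)
    logger.info("run: %d days x %s grid", len(temp.time), temp.grid.shape)
    thr = detection.compute_thresholds(
        temp,
        cfg.reference_period,
        cfg.percentiles,
        pool=cfg.threshold_pool,
        max_missing_fraction=cfg.max_missing_fraction,
    )
    years = sorted(set(temp.time.year.tolist()))
    paths: dict[str, Path] = {}
    all_events: list[detection.HeatwaveEvent] = []
    for p in cfg.percentiles:
        for mode in cfg.modes:
            evs = detection.extract_events(temp, thr, p, mode, cfg.min_run_days)
            logger.info("run: %d events at p%g (%s)", len(evs), p, mode)
            all_events.extend(evs)
    evrows = [
        {
            "cell_lat_idx": e.cell[0], "cell_lon_idx": e.cell[1],
            "start_date": e.start_date, "end_date": e.end_date,
            "year": e.year, "duration": e.duration,
            "peak_tmax": e.peak_tmax,
            "cumulative_exceedance": e.cumulative_exceedance,
            "mode": e.mode, "percentile": e.percentile,
        }
        for e in all_events
    ]
    evpath = outdir / "events.csv"
    export_csv(pd.DataFrame(evrows, columns=[
        "cell_lat_idx", "cell_lon_idx", "start_date", "end_date", "year",
        "duration", "peak_tmax", "cumulative_exceedance", "mode", "percentile",
    ]), evpath)
    paths["events"] = evpath

    series_by_p: dict[float, pd.DataFrame] = {}
    for p in cfg.percentiles:
        df = indices.index_timeseries(all_events, temp.grid, years, p, cfg.thw_stat)
        series_by_p[p] = df
        ipath = outdir / f"indices_p{p:g}.csv"
        export_csv(df, ipath)
        paths[f"indices_p{p:g}"] = ipath
        for mode in cfg.modes:
            paths[f"mask_p{p:g}_{mode}"] = _write_masks(
                temp, all_events, p, mode, years, outdir
            )

    ttable = trend.trend_table(series_by_p, alpha=0.05)
    tpath = outdir / "trend_table.csv"
    export_csv(ttable, tpath)
    paths["trend_table"] = tpath
    audit = {
        f"p{p:g}": {
            col: trend.mmk_test(
                df[col].to_numpy(dtype=float),
                bias_correction=cfg.bias_correction, ltp=cfg.ltp,
            ).__dict__
            for col in indices.INDEX_COLUMNS
        }
        for p, df in series_by_p.items()
    }
    apath = outdir / "trend_audit.json"
    apath.write_text(json.dumps(audit, indent=2, default=float) + "\n")
    paths["trend_audit"] = apath

    try:
        pops = _load_populations(cfg, outdir, temp.grid)
    except DataError:
        pops = {}
    if pops:
        exp_years = cfg.exposure_years or sorted(pops)
        frames = []
        for p in cfg.percentiles:
            es = exposure.exposure_series(
                all_events, pops, p, exp_years, cfg.exposure_mode,
                nearest_year=cfg.nearest_population_year,
            )
            frames.append(es.to_frame())
        epath = outdir / "exposure.csv"
        export_csv(pd.concat(frames, ignore_index=True), epath)
        paths["exposure"] = epath

    cfgpath = _dump_config(cfg, outdir)
    write_manifest(outdir, list(paths.values()) + [cfgpath])
    return paths


def report(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Time-series plots per index (one line per percentile), exposure plot
    and affected-area maps for the requested years."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    missing = [
        f
        for f in [outdir / f"indices_p{p:g}.csv" for p in cfg.percentiles]
        if not f.exists()
    ]
    if missing:
        raise DataError(f"report stage: missing outputs {[str(m) for m in missing]}")
    series = {p: pd.read_csv(outdir / f"indices_p{p:g}.csv") for p in cfg.percentiles}
    plotdir = outdir / "plots"
    plotdir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    colors = {95.0: "black", 97.5: "tab:blue", 99.0: "tab:red"}
    for col in indices.INDEX_COLUMNS:
        fig, ax = plt.subplots(figsize=(7, 3.2))
        for p, df in series.items():
            ax.plot(df["year"], df[col],
                    color=colors.get(p, None), label=f"> {p:g}th percentile")
        ax.set_xlabel("year")
        ax.set_ylabel(col)
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = plotdir / f"series_{col}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths[f"series_{col}"] = path

    exp = outdir / "exposure.csv"
    if exp.exists():
        df = pd.read_csv(exp)
        fig, ax = plt.subplots(figsize=(7, 3.2))
        for p, sub in df.groupby("percentile"):
            ax.plot(sub["year"], sub["affected_population"],
                    color=colors.get(float(p), None), label=f"> {p:g}th percentile")
        ax.set_xlabel("year")
        ax.set_ylabel("affected population (persons)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = plotdir / "exposure_series.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths["exposure_series"] = path

    for p in cfg.percentiles:
        mask_nc = outdir / f"affected_mask_p{p:g}_day.nc"
        if not mask_nc.exists():
            continue
        ds = xr.open_dataset(mask_nc, engine="scipy")
        years = cfg.report_map_years or [int(y) for y in ds["year"].values if y % 10 == 0]
        for y in years:
            if y not in ds["year"].values:
                continue
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.pcolormesh(
                ds["lon"], ds["lat"], ds["affected"].sel(year=y),
                vmin=0, vmax=1, cmap="Reds",
            )
            ax.set_title(f"affected cells {y}, >{p:g}th pct")
            fig.tight_layout()
            path = plotdir / f"map_affected_p{p:g}_{y}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            paths[f"map_p{p:g}_{y}"] = path
        ds.close()
    return paths
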