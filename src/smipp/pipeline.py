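"""End-to-end orchestration: simulate/read → smooth → indicators → fit →
attribute → climate sensitivity.

The same stage logic serves both data paths:

* **grid** — 8-day composites per pixel, smoothed by the degree-6 seasonal
  polynomial, looped over pixels into maps;
* **site** — daily series, smoothed by SSA.

Every run writes a machine-readable manifest (resolved configuration, a
content digest of each output, package/library versions and per-stage record
counts) whose overall hash is reproducible for a fixed seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import xarray as xr

from . import io as sio
from .attribution import iav_contributions, ols_trend, spatial_correlation, trend_contributions
from .calendar import COMPOSITE_MID_DOYS
from .climate import partial_correlation, preseason_aggregate, sensitivity, summer_aggregate
from .config import PipelineConfig
from .errors import ConfigError, SmippError
from .indicators import annual_gpp, compute_threshold, extract_indicators, records_to_frame
from .model import build_anomalies, check_independence, fit_smipp
from .smoothing import evaluate_curve, fit_seasonal_polynomial, ssa_smooth
from .synthetic import ClimateSeries, SeasonalSeries, TruthParams, generate_grid, generate_site_years

__all__ = ["extract_records", "analyze_location", "run_pipeline"]

log = logging.getLogger("smipp")

INDICATORS = ("gs_start", "gpp_max", "gs_end")
CLIMATE_VARS = ("temperature", "precipitation", "radiation")


def _smooth_year(values: np.ndarray, cadence: str, config: PipelineConfig, year: int):
    if cadence == "8day":
        curve = fit_seasonal_polynomial(values, COMPOSITE_MID_DOYS, config.poly_degree, year)
        return evaluate_curve(curve)
    return ssa_smooth(values, config.ssa_window, config.ssa_components, year)


def extract_records(series: SeasonalSeries, config: PipelineConfig) -> pd.DataFrame:
    """Indicator table for one pixel/site.

    Two passes: the yearly smoothed curves first supply the peak values whose
    long-term mean defines the 10 % threshold, then the indicators are read
    off each curve against that shared threshold.  Annual totals come from
    the raw (unsmoothed) series.  Years whose smoothing fails are kept as
    invalid rows rather than dropped silently.
    """
    curves, failed = {}, set()
    for i, year in enumerate(series.years):
        try:
            curves[int(year)] = _smooth_year(series.values[i], series.cadence, config, int(year))
        except SmippError:
            failed.add(int(year))
    if not curves:
        raise SmippError("no year could be smoothed")

    peaks = []
    for curve in curves.values():
        lo, hi = (15, 350) if curve.method == "polynomial" else (1, 365)
        peaks.append(np.maximum(curve.values[lo - 1:hi], 0.0).max())
    threshold = compute_threshold(peaks, config.threshold_fraction)

    records = []
    for i, year in enumerate(series.years):
        year = int(year)
        raw = series.values[i]
        annual = annual_gpp(raw, series.cadence) if np.isfinite(raw).all() else np.nan
        if year in failed:
            records.append(
                dict(year=year, gs_start=np.nan, gpp_max=np.nan, doy_of_max=np.nan,
                     gs_end=np.nan, annual_gpp=annual, valid=False)
            )
            continue
        rec = extract_indicators(
            curves[year], threshold, annual=annual, crossing_rule=config.crossing_rule
        )
        records.append(vars(rec))
    frame = pd.DataFrame(records)
    frame.attrs["threshold"] = threshold.threshold
    return frame


def _climate_aggregates(climate: ClimateSeries, means: pd.Series, config: PipelineConfig):
    """Per-year climate aggregates for each indicator's own season."""
    out = {}
    for var in CLIMATE_VARS:
        daily = getattr(climate, var)
        out[("gs_start", var)] = preseason_aggregate(
            daily, means["gs_start"], config.preseason_window
        )
        out[("gs_end", var)] = preseason_aggregate(
            daily, means["gs_end"], config.preseason_window
        )
        mode = config.summer_precip_mode if var == "precipitation" else "mean"
        out[("gpp_max", var)] = summer_aggregate(daily, mode)
    return out


def analyze_location(
    records: pd.DataFrame,
    climate: ClimateSeries | None,
    config: PipelineConfig,
) -> dict:
    """Full per-location analysis from an indicator table.

    Returns a dict with the anomaly table, the fitted sensitivities, the
    per-year decomposition, raw-indicator and component trends, trend- and
    IAV-mode contributions, and (when climate is given) the indicator–climate
    sensitivity table and partial correlations with temperature.
    """
    table = build_anomalies(records, config.min_years)
    fit = fit_smipp(table, min_years=config.min_years)
    years = table.data.index.to_numpy(dtype=float)
    comp = fit.components

    trends = {
        name: ols_trend(years, table.data["d_gpp"] if name == "annual_gpp"
                        else records.set_index("year").loc[table.data.index, name])
        for name in ("annual_gpp", *INDICATORS)
    }
    comp_trends = {c: ols_trend(years, comp[c]) for c in ("start", "max", "end")}
    gpp_trend = trends["annual_gpp"].slope
    contrib_trend = trend_contributions(
        comp_trends["start"].slope, comp_trends["max"].slope,
        comp_trends["end"].slope, gpp_trend,
    )
    reference = table.data["d_gpp"].to_numpy() if config.iav_reference == "observed" else None
    contrib_iav = iav_contributions(
        comp["start"].to_numpy(), comp["max"].to_numpy(), comp["end"].to_numpy(),
        reference=reference,
    )

    result = {
        "table": table,
        "fit": fit,
        "independence": check_independence(table),
        "trends": trends,
        "component_trends": comp_trends,
        "contrib_trend": contrib_trend,
        "contrib_iav": contrib_iav,
    }

    if climate is not None:
        aligned = records.set_index("year").loc[table.data.index]
        year_pos = {int(y): i for i, y in enumerate(climate.years)}
        pos = np.array([year_pos[int(y)] for y in table.data.index])
        aggs = _climate_aggregates(climate, table.means, config)
        rows = []
        pcorr = {}
        for ind in INDICATORS:
            per_var = {var: aggs[(ind, var)][pos] for var in CLIMATE_VARS}
            for var in CLIMATE_VARS:
                try:
                    s = sensitivity(aligned[ind].to_numpy(), per_var[var], config.min_years)
                    rows.append(dict(indicator=ind, climate=var, r=s.r, slope=s.slope,
                                     p_value=s.p_value, n=s.n))
                except SmippError:
                    rows.append(dict(indicator=ind, climate=var, r=np.nan, slope=np.nan,
                                     p_value=np.nan, n=0))
            try:
                controls = np.column_stack([per_var["precipitation"], per_var["radiation"]])
                pcorr[ind] = partial_correlation(
                    aligned[ind].to_numpy(), per_var["temperature"], controls
                )
            except SmippError:
                pcorr[ind] = (np.nan, np.nan)
        result["sensitivity"] = pd.DataFrame(rows)
        result["partial_corr_temperature"] = pcorr
    return result


# ---------------------------------------------------------------------------
# gridded path


_MAP_FIELDS = [
    "eta_start", "eta_max", "eta_end", "r2", "p_start", "p_max", "p_end",
    "trend_gpp", "trend_gs_start", "trend_gpp_max", "trend_gs_end",
    "c_start_trend", "c_max_trend", "c_end_trend",
    "c_start_iav", "c_max_iav", "c_end_iav",
]


def process_grid(gpp_ds: xr.Dataset, clim_ds: xr.Dataset | None, config: PipelineConfig):
    """Per-pixel analysis over a gridded 8-day product.

    Returns ``(maps, records_frame, summary)``: an xarray Dataset of fit /
    trend / contribution / sensitivity maps, the stacked per-pixel indicator
    tables, and a summary dict (spatial correlations of the trend maps,
    regional means of the sensitivities and shares).
    """
    ny, nx = gpp_ds.sizes["y"], gpp_ds.sizes["x"]
    maps = {name: np.full((ny, nx), np.nan) for name in _MAP_FIELDS}
    sens_maps = {
        f"{stat}_{ind}_{var}": np.full((ny, nx), np.nan)
        for ind in INDICATORS for var in CLIMATE_VARS for stat in ("r", "slope", "p")
    }
    all_records = []
    n_failed = 0
    for iy in range(ny):
        for ix in range(nx):
            series = sio.pixel_gpp_series(gpp_ds, iy, ix)
            climate = sio.pixel_climate_series(clim_ds, iy, ix) if clim_ds is not None else None
            try:
                records = extract_records(series, config)
                res = analyze_location(records, climate, config)
            except SmippError as exc:
                n_failed += 1
                log.warning("pixel (%d, %d) skipped: %s", iy, ix, exc)
                continue
            all_records.append(records.assign(y=iy, x=ix))
            fit = res["fit"]
            m = maps
            m["eta_start"][iy, ix] = fit.eta_start
            m["eta_max"][iy, ix] = fit.eta_max
            m["eta_end"][iy, ix] = fit.eta_end
            m["r2"][iy, ix] = fit.r_squared
            for k in ("start", "max", "end"):
                m[f"p_{k}"][iy, ix] = fit.p_values[k]
            m["trend_gpp"][iy, ix] = res["trends"]["annual_gpp"].slope
            for ind in INDICATORS:
                m[f"trend_{ind}"][iy, ix] = res["trends"][ind].slope
            for k in ("start", "max", "end"):
                m[f"c_{k}_trend"][iy, ix] = getattr(res["contrib_trend"], f"c_{k}")
                m[f"c_{k}_iav"][iy, ix] = getattr(res["contrib_iav"], f"c_{k}")
            if "sensitivity" in res:
                for _, row in res["sensitivity"].iterrows():
                    key = f"{row['indicator']}_{row['climate']}"
                    sens_maps[f"r_{key}"][iy, ix] = row["r"]
                    sens_maps[f"slope_{key}"][iy, ix] = row["slope"]
                    sens_maps[f"p_{key}"][iy, ix] = row["p_value"]

    coords = {"y": np.arange(ny), "x": np.arange(nx)}
    data = {k: (("y", "x"), v) for k, v in {**maps, **sens_maps}.items()}
    map_ds = xr.Dataset(data, coords=coords)

    summary: dict = {"n_pixels": ny * nx, "n_failed": n_failed}
    try:
        for ind in INDICATORS:
            r2, p = spatial_correlation(maps["trend_gpp"], maps[f"trend_{ind}"])
            summary[f"spatial_r2_trend_gpp_vs_{ind}"] = r2
            summary[f"spatial_p_trend_gpp_vs_{ind}"] = p
    except SmippError:
        pass  # grids smaller than 10 pixels
    for name in ("eta_start", "eta_max", "eta_end", "r2",
                 "c_start_iav", "c_max_iav", "c_end_iav"):
        vals = maps[name][np.isfinite(maps[name])]
        if vals.size:
            summary[f"mean_{name}"] = float(vals.mean())
            summary[f"sd_{name}"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    cmax = maps["c_max_iav"]
    finite = np.isfinite(cmax)
    if finite.any():
        summary["area_fraction_c_max_iav_gt_50"] = float((np.abs(cmax[finite]) > 50).mean())
    records_frame = pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame()
    return map_ds, records_frame, summary


# ---------------------------------------------------------------------------
# run + manifest


def _digest(arr: np.ndarray) -> str:
    a = np.ascontiguousarray(np.round(np.asarray(arr, dtype=float), 9))
    return hashlib.sha256(a.tobytes()).hexdigest()


def _dataset_digest(ds: xr.Dataset) -> str:
    h = hashlib.sha256()
    for name in sorted(ds.data_vars):
        h.update(name.encode())
        h.update(_digest(ds[name].values).encode())
    return h.hexdigest()


def _pixel_params(config: PipelineConfig) -> list[TruthParams]:
    ny, nx = config.grid_shape
    children = np.random.SeedSequence(config.seed).spawn(ny * nx)
    return [
        TruthParams(
            n_years=config.n_years,
            seed=int(c.generate_state(1)[0] % (2**31)),
            **config.truth_overrides,
        )
        for c in children
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write its products and manifest.

    Grid mode writes ``fits.nc`` (all maps), ``indicators.csv`` and
    ``manifest.json`` into ``config.out_dir``; site mode writes the per-site
    tables as CSV.  When no input paths are configured the synthetic
    generator supplies the data (and the ground-truth table is written too).
    """
    t0 = time.perf_counter()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "versions": _versions(), "outputs": {}}
    bundle: dict = {"config": config}

    if config.mode == "grid":
        if config.gpp_path:
            gpp_ds = sio.read_grid(config.gpp_path, "gpp")
            clim_ds = sio.read_grid(config.climate_path) if config.climate_path else None
        else:
            params = _pixel_params(config)
            gpp_ds, clim_ds, truth = generate_grid(
                params, config.grid_shape, config.preseason_window
            )
            _write_csv(truth, os.path.join(config.out_dir, "truth.csv"), config.overwrite)
            bundle["truth"] = truth
            manifest["outputs"]["truth.csv"] = _digest(
                truth.select_dtypes("number").to_numpy()
            )
        log.info("input ready (%.2fs)", time.perf_counter() - t0)
        map_ds, records, summary = process_grid(gpp_ds, clim_ds, config)
        fits_path = os.path.join(config.out_dir, "fits.nc")
        if os.path.exists(fits_path) and not config.overwrite:
            raise ConfigError(f"refusing to overwrite {fits_path!r}")
        if os.path.exists(fits_path):
            os.remove(fits_path)
        sio.write_grid(map_ds, fits_path)
        _write_csv(records, os.path.join(config.out_dir, "indicators.csv"), config.overwrite)
        manifest["outputs"]["fits.nc"] = _dataset_digest(map_ds)
        manifest["outputs"]["indicators.csv"] = _digest(
            records.drop(columns=["valid"]).to_numpy(dtype=float)
        )
        manifest["summary"] = _jsonable(summary)
        manifest["counts"] = {"pixels": summary["n_pixels"], "records": len(records)}
        bundle.update({"maps": map_ds, "records": records, "summary": summary})
    else:
        if config.gpp_path:
            series, climate = sio.read_site_csv(config.gpp_path)
        else:
            params = TruthParams(
                n_years=config.n_years, seed=config.seed, **config.truth_overrides
            )
            series, climate, truth = generate_site_years(params, config.preseason_window)
            _write_csv(truth, os.path.join(config.out_dir, "truth.csv"), config.overwrite)
            bundle["truth"] = truth
        records = extract_records(series, config)
        res = analyze_location(records, climate, config)
        _write_csv(records, os.path.join(config.out_dir, "indicators.csv"), config.overwrite)
        fit = res["fit"]
        fit_row = pd.DataFrame(
            [dict(eta_start=fit.eta_start, eta_max=fit.eta_max, eta_end=fit.eta_end,
                  intercept=fit.intercept, r2=fit.r_squared, n_years=fit.n_years,
                  p_start=fit.p_values["start"], p_max=fit.p_values["max"],
                  p_end=fit.p_values["end"],
                  c_start_trend=res["contrib_trend"].c_start,
                  c_max_trend=res["contrib_trend"].c_max,
                  c_end_trend=res["contrib_trend"].c_end,
                  c_start_iav=res["contrib_iav"].c_start,
                  c_max_iav=res["contrib_iav"].c_max,
                  c_end_iav=res["contrib_iav"].c_end)]
        )
        _write_csv(fit_row, os.path.join(config.out_dir, "fit.csv"), config.overwrite)
        _write_csv(fit.components.reset_index(),
                   os.path.join(config.out_dir, "components.csv"), config.overwrite)
        if "sensitivity" in res:
            _write_csv(res["sensitivity"],
                       os.path.join(config.out_dir, "sensitivity.csv"), config.overwrite)
        manifest["outputs"]["indicators.csv"] = _digest(
            records.drop(columns=["valid"]).to_numpy(dtype=float)
        )
        manifest["outputs"]["fit.csv"] = _digest(fit_row.to_numpy(dtype=float))
        manifest["counts"] = {"records": len(records), "usable_years": fit.n_years}
        bundle.update({"records": records, "result": res})

    # The hash covers the scientific content, not where it was written:
    # output locations and overwrite policy are excluded so identical seeded
    # runs agree regardless of their target directory.
    hashed = dict(manifest, config={
        k: v for k, v in manifest["config"].items()
        if k not in ("out_dir", "overwrite", "gpp_path", "climate_path")
    })
    payload = json.dumps(hashed, sort_keys=True, default=str).encode()
    manifest["manifest_hash"] = hashlib.sha256(payload).hexdigest()
    man_path = os.path.join(config.out_dir, "manifest.json")
    if os.path.exists(man_path) and not config.overwrite:
        raise ConfigError(f"refusing to overwrite {man_path!r}")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    bundle["manifest"] = manifest
    return bundle


def _write_csv(frame: pd.DataFrame, path: str, overwrite: bool) -> None:
    if os.path.exists(path) and not overwrite:
        raise ConfigError(f"refusing to overwrite {path!r}")
    frame.to_csv(path, index=False)


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "smipp": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "xarray": xr.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _jsonable(d: dict) -> dict:
    return {k: (float(v) if isinstance(v, (np.floating, float)) else v) for k, v in d.items()}
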