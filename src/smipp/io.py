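"""Readers and writers for the formats the pipeline touches.

Gridded data travel as NetCDF (written through xarray's scipy backend,
NetCDF3 classic — dims ``time, y, x``, CF-style units attributes); site
data as plain CSV with columns ``date, gpp[, temperature, precipitation,
radiation]``.  Missing values in CSVs may be empty fields, ``NA`` or
``-9999``.  All series are mapped onto the fixed 365-day calendar: leap
days are dropped on read.

Writers refuse to overwrite an existing file unless ``force`` is set.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd
import xarray as xr

from .calendar import DAYS_PER_YEAR
from .errors import FormatError
from .synthetic import ClimateSeries, SeasonalSeries

__all__ = [
    "write_grid",
    "read_grid",
    "write_site_csv",
    "read_site_csv",
    "pixel_gpp_series",
    "pixel_climate_series",
]

MISSING_CODES = ("", "NA", "NaN", "-9999", "-9999.0")

CLIMATE_COLS = ("temperature", "precipitation", "radiation")


def _refuse_overwrite(path: str, force: bool) -> None:
    if os.path.exists(path) and not force:
        raise FormatError(f"refusing to overwrite existing file {path!r} (use force)")


def write_grid(ds: xr.Dataset, path: str, force: bool = False) -> None:
    """Write a gridded dataset as NetCDF3 (classic)."""
    _refuse_overwrite(path, force)
    ds.to_netcdf(path, engine="scipy")


def read_grid(path: str, variable: str | None = None) -> xr.Dataset:
    """Read a gridded NetCDF file and validate its layout.

    Requires a strictly increasing ``time`` axis and at least one of the
    known data variables (``gpp`` or the climate triplet) unless ``variable``
    names the one that must be present.
    """
    try:
        ds = xr.open_dataset(path, engine="scipy").load()
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read NetCDF file {path!r}: {exc}") from exc
    if "time" not in ds.coords and "time" not in ds.dims:
        raise FormatError(f"{path!r}: missing required axis 'time'")
    t = ds["time"].values
    if t.size > 1 and not (np.diff(t.astype("datetime64[ns]").astype(np.int64)) > 0).all():
        raise FormatError(f"{path!r}: time axis is not strictly increasing")
    known = {"gpp", *CLIMATE_COLS}
    present = known & set(ds.data_vars)
    if variable is not None:
        if variable not in ds.data_vars:
            raise FormatError(f"{path!r}: missing required variable {variable!r}")
    elif not present:
        raise FormatError(f"{path!r}: none of the expected variables {sorted(known)} present")
    return ds


def write_site_csv(
    series: SeasonalSeries,
    path: str,
    climate: ClimateSeries | None = None,
    force: bool = False,
) -> None:
    """Write a daily site series (and optionally climate) as CSV."""
    if series.cadence != "daily":
        raise FormatError("site CSVs are daily; aggregate separately for 8-day data")
    _refuse_overwrite(path, force)
    from .calendar import dates_from_year_doy

    n_years = len(series.years)
    years = np.repeat(series.years, DAYS_PER_YEAR)
    doys = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    frame = pd.DataFrame(
        {
            "date": dates_from_year_doy(years, doys).astype("datetime64[D]").astype(str),
            "gpp": series.values.ravel(),
        }
    )
    if climate is not None:
        for col in CLIMATE_COLS:
            frame[col] = getattr(climate, col).ravel()
    # %.17g keeps doubles bit-exact through the text round trip.
    frame.to_csv(path, index=False, float_format="%.17g")


def _dense_year_grid(df: pd.DataFrame, col: str, years: np.ndarray) -> np.ndarray:
    out = np.full((years.size, DAYS_PER_YEAR), np.nan)
    yi = {int(y): i for i, y in enumerate(years)}
    rows = df["year"].map(yi).to_numpy()
    out[rows, df["doy"].to_numpy() - 1] = df[col].to_numpy(dtype=float)
    return out


def read_site_csv(path: str) -> tuple[SeasonalSeries, ClimateSeries | None]:
    """Read a daily site CSV onto the fixed 365-day calendar.

    Leap days (Feb 29) are dropped; DOYs after Feb 28 in leap years shift
    back one day so every year has exactly 365 slots.  Days absent from the
    file, or coded as missing, become NaN.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "date" not in df.columns or "gpp" not in df.columns:
        raise FormatError(f"{path!r}: CSV must have 'date' and 'gpp' columns")
    dates = pd.to_datetime(df["date"], format="mixed", errors="coerce")
    if dates.isna().any():
        line = int(np.nonzero(dates.isna().to_numpy())[0][0]) + 2  # 1-based + header
        raise FormatError(f"{path!r}: unparseable date at line {line}")
    df = df.assign(_date=dates)
    df = df[~((dates.dt.month == 2) & (dates.dt.day == 29))].copy()
    doy = df["_date"].dt.dayofyear.to_numpy()
    leap = df["_date"].dt.is_leap_year.to_numpy()
    df["doy"] = np.where(leap & (doy > 60), doy - 1, doy)
    df["year"] = df["_date"].dt.year.to_numpy()

    def _parse(value: str) -> float:
        # Python's float parser is exact to the last bit (pandas' fast C
        # parser is not, which would break round-trip fidelity).
        value = value.strip()
        if value in MISSING_CODES:
            return np.nan
        try:
            return float(value)
        except ValueError:
            return np.nan

    numeric_cols = ["gpp"] + [c for c in CLIMATE_COLS if c in df.columns]
    for col in numeric_cols:
        df[col] = df[col].map(_parse)

    years = np.array(sorted(df["year"].unique()))
    series = SeasonalSeries(_dense_year_grid(df, "gpp", years), years, "daily")
    climate = None
    if all(c in df.columns for c in CLIMATE_COLS):
        climate = ClimateSeries(
            *(_dense_year_grid(df, c, years) for c in CLIMATE_COLS), years
        )
    return series, climate


def pixel_gpp_series(ds: xr.Dataset, iy: int, ix: int) -> SeasonalSeries:
    """One pixel of a gridded 8-day GPP dataset as a SeasonalSeries."""
    sub = ds["gpp"].isel(y=iy, x=ix)
    years = np.unique(ds["year"].values)
    vals = sub.values.reshape(years.size, -1)
    return SeasonalSeries(vals, years, "8day")


def pixel_climate_series(ds: xr.Dataset, iy: int, ix: int) -> ClimateSeries:
    """One pixel of a gridded daily climate dataset as a ClimateSeries."""
    years = np.unique(ds["year"].values)
    arrs = [
        ds[c].isel(y=iy, x=ix).values.reshape(years.size, DAYS_PER_YEAR)
        for c in CLIMATE_COLS
    ]
    return ClimateSeries(*arrs, years)
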