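"""Synthetic GPP and climate generator with bit-defined ground truth.

Every downstream stage of the pipeline (smoothing, indicator extraction, the
anomaly regression, attribution, climate sensitivity) is tested against data
from this module, because the real gridded GPP products and flux-tower records
it emulates are not redistributable.  The generator therefore does two things
at once:

* it produces daily (site-like) and 8-day gridded (satellite-product-like)
  GPP series with a realistic seasonal cycle, long-term trends, inter-annual
  variability, climate couplings and observation noise;
* it records the exact ground truth — per-year growing-season start
  (``gs_start``), peak daily GPP (``gpp_max``), growing-season end
  (``gs_end``), the exact annual integral of the noise-free curve, and the
  temperature anomalies that drive the couplings — so that recovery can be
  asserted, not eyeballed.

The seasonal curve family is a symmetric sine-power bump whose 10 %-of-peak
crossing days are placed analytically at ``gs_start`` and ``gs_end``; the
threshold crossings that the indicator-extraction stage must find are thus
exact by construction rather than themselves estimated.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .calendar import (
    DAYS_PER_YEAR,
    JJA_END_DOY,
    JJA_START_DOY,
    aggregate_daily_to_8day,
    dates_from_year_doy,
)
from .errors import InvalidParametersError

__all__ = [
    "TruthParams",
    "SeasonalSeries",
    "ClimateSeries",
    "generate_seasonal_curve",
    "generate_site_years",
    "generate_grid",
]

#: Exponent of the sine-power bump.  Fixed rather than tunable: the 10 %
#: crossings are solved analytically for this exponent.
BUMP_EXPONENT = 2.0

# Seasonal temperature cycle: mean + amplitude * sin, peaking around DOY 196
# (mid July), broadly a temperate / boreal Northern-Hemisphere annual cycle.
TEMP_MEAN = 8.0
TEMP_AMPLITUDE = 14.0
TEMP_PHASE_DOY = 105.0

RAD_MEAN = 250.0
RAD_AMPLITUDE = 120.0
RAD_NOISE_SD = 30.0

PRECIP_GAMMA_SHAPE = 0.8
PRECIP_GAMMA_SCALE = 3.0


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters for one site or pixel.

    Units: days (DOY) for phenology, g C m⁻² d⁻¹ for daily GPP, per-year for
    trends, days °C⁻¹ / g C m⁻² d⁻¹ °C⁻¹ for temperature couplings.  A
    negative ``temp_sens_gs_start`` means the season starts earlier in warm
    years (the usual spring response); a positive ``temp_sens_gs_end`` means
    it ends later.

    The defaults describe a temperate/boreal North-American pixel consistent
    with the regional means the pipeline is benchmarked against: season from
    late April (DOY 120) to early October (DOY 280), peak daily GPP
    8 g C m⁻² d⁻¹, a spring advance of −1.9 d °C⁻¹ and an autumn delay of
    +1.7 d °C⁻¹ against preseason temperature, a modest positive coupling of
    the peak to summer temperature, and 15 years of record.
    """

    mean_gs_start: float = 120.0
    mean_gs_end: float = 280.0
    mean_gpp_max: float = 8.0
    trend_gs_start: float = 0.0
    trend_gs_end: float = 0.0
    trend_gpp_max: float = 0.0
    iav_sd_gs_start: float = 3.0
    iav_sd_gs_end: float = 3.0
    iav_sd_gpp_max: float = 0.4
    temp_sens_gs_start: float = -1.9
    temp_sens_gs_end: float = 1.7
    temp_sens_gpp_max: float = 0.33
    temp_anom_sd: float = 1.5
    obs_noise_sd: float = 0.5
    n_years: int = 15
    start_year: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_gs_start < self.mean_gs_end:
            raise InvalidParametersError(
                f"mean_gs_start ({self.mean_gs_start}) must precede mean_gs_end ({self.mean_gs_end})"
            )
        if self.mean_gpp_max <= 0:
            raise InvalidParametersError("mean_gpp_max must be positive")
        if self.n_years < 3:
            raise InvalidParametersError("need at least 3 years")
        for name in ("iav_sd_gs_start", "iav_sd_gs_end", "iav_sd_gpp_max",
                     "temp_anom_sd", "obs_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParametersError(f"{name} must be non-negative")


@dataclass
class SeasonalSeries:
    """A multi-year GPP series on the fixed 365-day calendar.

    ``values`` has shape (n_years, 365) for daily cadence or (n_years, 46)
    for 8-day composites; ``years`` are the calendar-year labels.
    """

    values: np.ndarray
    years: np.ndarray
    cadence: str  # "daily" | "8day"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years)
        steps = {"daily": DAYS_PER_YEAR, "8day": 46}
        if self.cadence not in steps:
            raise InvalidParametersError(f"unknown cadence {self.cadence!r}")
        if self.values.ndim != 2 or self.values.shape != (len(self.years), steps[self.cadence]):
            raise InvalidParametersError(
                f"values must have shape (n_years, {steps[self.cadence]})"
            )


@dataclass
class ClimateSeries:
    """Daily temperature (°C), precipitation (mm d⁻¹) and downward solar
    radiation (W m⁻²), each of shape (n_years, 365)."""

    temperature: np.ndarray
    precipitation: np.ndarray
    radiation: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.years), DAYS_PER_YEAR)
        for name in ("temperature", "precipitation", "radiation"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != shape:
                raise InvalidParametersError(f"{name} must have shape {shape}")


def _bump_half_width(half_span: float, exponent: float = BUMP_EXPONENT) -> float:
    # Solve sin(pi*(H-h)/(2H))**q = 0.1 for the half-width H of the support,
    # given half the start-to-end span h.  H > h, so the support is slightly
    # wider than [gs_start, gs_end].
    a = np.arcsin(0.1 ** (1.0 / exponent))
    return np.pi * half_span / (np.pi - 2.0 * a)


def generate_seasonal_curve(
    gs_start: float, gs_end: float, gpp_max: float
) -> np.ndarray:
    """Noise-free daily GPP curve (365 values, DOY 1..365).

    A symmetric sine-power bump: zero outside its support, peak ``gpp_max``
    at the midpoint of [gs_start, gs_end], and exactly 10 % of ``gpp_max``
    at DOY ``gs_start`` (rising) and ``gs_end`` (falling).

    ``gpp_max = 0`` yields the all-zero curve.
    """
    if gs_start >= gs_end:
        raise InvalidParametersError(f"gs_start ({gs_start}) must precede gs_end ({gs_end})")
    if gpp_max < 0:
        raise InvalidParametersError("gpp_max must be non-negative")
    doy = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)
    mid = 0.5 * (gs_start + gs_end)
    H = _bump_half_width(0.5 * (gs_end - gs_start))
    u = np.pi * (doy - (mid - H)) / (2.0 * H)
    inside = (u > 0.0) & (u < np.pi)
    curve = np.zeros(DAYS_PER_YEAR)
    curve[inside] = gpp_max * np.sin(u[inside]) ** BUMP_EXPONENT
    return curve


#: Days by which the generator extends each constant temperature anomaly
#: beyond its aggregation window on both sides.  Real anomalies persist for
#: days rather than switching off at a window edge; the padding also keeps
#: coupling recovery unbiased when the recovered mean dates that anchor the
#: aggregation windows are off by a day or two.
ANOMALY_PAD_DAYS = 5


def _window_doys(mean_date: float, window: int, pad: int = 0) -> slice:
    # 0-based day slice of the `window` days preceding mean_date,
    # optionally padded on both sides (clipped to the year).
    end = int(round(mean_date))  # exclusive, 1-based DOY of the mean date
    start = end - window
    if start < 1:
        raise InvalidParametersError(
            f"preseason window before DOY {mean_date} spills into the previous year"
        )
    return slice(max(start - 1 - pad, 0), min(end - 1 + pad, DAYS_PER_YEAR))


def _seasonal_temperature(doy: np.ndarray) -> np.ndarray:
    return TEMP_MEAN + TEMP_AMPLITUDE * np.sin(
        2.0 * np.pi * (doy - TEMP_PHASE_DOY) / DAYS_PER_YEAR
    )


def generate_site_years(
    params: TruthParams, preseason_window: int = 30
) -> tuple[SeasonalSeries, ClimateSeries, pd.DataFrame]:
    """Generate one site's daily GPP, daily climate, and its truth table.

    Per year ``t`` (0-based) the indicator truths are

        indicator_t = mean + trend * t + temp_sens * A_t + N(0, iav_sd)

    where ``A_t`` is that indicator's own window-mean temperature anomaly:
    the mean of the ``preseason_window`` days before the long-term mean
    ``gs_start`` date (for the start), before the mean ``gs_end`` date (for
    the end), and June–August (for the peak).  The daily temperature series
    carries exactly these anomalies on top of a fixed seasonal sinusoid, so
    regressing recovered indicators on the aggregated windows is an unbiased
    estimate of the prescribed sensitivities.

    Daily GPP is the exact bump for the year's truth indicators plus additive
    Gaussian observation noise, clipped at zero.  The truth table records the
    exact annual integral of each noise-free curve.

    Returns ``(gpp, climate, truth)``; deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_years
    years = params.start_year + np.arange(n)
    doy = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)

    anom_start = rng.normal(0.0, params.temp_anom_sd, n)
    anom_end = rng.normal(0.0, params.temp_anom_sd, n)
    anom_summer = rng.normal(0.0, params.temp_anom_sd, n)
    iav_start = rng.normal(0.0, params.iav_sd_gs_start, n)
    iav_end = rng.normal(0.0, params.iav_sd_gs_end, n)
    iav_max = rng.normal(0.0, params.iav_sd_gpp_max, n)

    t = np.arange(n)
    gs_start = params.mean_gs_start + params.trend_gs_start * t \
        + params.temp_sens_gs_start * anom_start + iav_start
    gs_end = params.mean_gs_end + params.trend_gs_end * t \
        + params.temp_sens_gs_end * anom_end + iav_end
    gpp_max = params.mean_gpp_max + params.trend_gpp_max * t \
        + params.temp_sens_gpp_max * anom_summer + iav_max

    if np.any(gs_start >= gs_end) or np.any(gpp_max <= 0):
        raise InvalidParametersError(
            "generated year has gs_start >= gs_end or non-positive gpp_max; "
            "reduce trends/IAV or widen the mean season"
        )

    pad = ANOMALY_PAD_DAYS
    sl_start = _window_doys(params.mean_gs_start, preseason_window, pad)
    sl_end = _window_doys(params.mean_gs_end, preseason_window, pad)
    # The JJA window is fixed by the calendar, so its aggregate cannot be
    # misaligned — no padding, which also keeps it clear of the end-preseason
    # window.
    sl_jja = slice(JJA_START_DOY - 1, JJA_END_DOY)

    gpp = np.empty((n, DAYS_PER_YEAR))
    temp = np.empty((n, DAYS_PER_YEAR))
    annual_truth = np.empty(n)
    seasonal_t = _seasonal_temperature(doy)
    for i in range(n):
        clean = generate_seasonal_curve(gs_start[i], gs_end[i], gpp_max[i])
        annual_truth[i] = clean.sum()
        noise = rng.normal(0.0, params.obs_noise_sd, DAYS_PER_YEAR) \
            if params.obs_noise_sd > 0 else 0.0
        gpp[i] = np.maximum(clean + noise, 0.0)
        temp[i] = seasonal_t
        temp[i, sl_start] += anom_start[i]
        temp[i, sl_end] += anom_end[i]
        temp[i, sl_jja] += anom_summer[i]

    precip = rng.gamma(PRECIP_GAMMA_SHAPE, PRECIP_GAMMA_SCALE, (n, DAYS_PER_YEAR))
    rad = np.maximum(
        RAD_MEAN
        + RAD_AMPLITUDE * np.sin(2.0 * np.pi * (doy - TEMP_PHASE_DOY) / DAYS_PER_YEAR)
        + rng.normal(0.0, RAD_NOISE_SD, (n, DAYS_PER_YEAR)),
        0.0,
    )

    truth = pd.DataFrame(
        {
            "year": years,
            "gs_start": gs_start,
            "gpp_max": gpp_max,
            "gs_end": gs_end,
            "annual_gpp": annual_truth,
            "temp_anom_start": anom_start,
            "temp_anom_end": anom_end,
            "temp_anom_summer": anom_summer,
        }
    )
    series = SeasonalSeries(gpp, years, "daily")
    climate = ClimateSeries(temp, precip, rad, years)
    return series, climate, truth


def _as_param_array(params: Sequence, shape: tuple[int, int]) -> np.ndarray:
    ny, nx = shape
    arr = np.empty(ny * nx, dtype=object)
    flat = list(np.asarray(params, dtype=object).ravel())
    if len(flat) != ny * nx:
        raise InvalidParametersError(
            f"params grid has {len(flat)} entries, expected {ny * nx} for shape {shape}"
        )
    arr[:] = flat
    return arr.reshape(shape)


def generate_grid(
    params: Sequence, shape: tuple[int, int], preseason_window: int = 30
) -> tuple[xr.Dataset, xr.Dataset, pd.DataFrame]:
    """Generate a gridded 8-day GPP product plus daily gridded climate.

    ``params`` is a flat or nested sequence of :class:`TruthParams`, one per
    pixel in row-major (y, x) order; all pixels must share ``n_years`` and
    ``start_year``.  Daily per-pixel curves are averaged into 46 8-day
    composites per year (the last composite covers 5 days).  Pixels are
    mutually independent (each uses its own seed).

    Returns ``(gpp_dataset, climate_dataset, truth_table)`` where the truth
    table carries the per-pixel, per-year indicator ground truth with ``y``
    and ``x`` index columns.
    """
    grid = _as_param_array(params, shape)
    ny, nx = shape
    p0 = grid[0, 0]
    n, y0 = p0.n_years, p0.start_year
    for p in grid.ravel():
        if p.n_years != n or p.start_year != y0:
            raise InvalidParametersError("all pixels must share n_years and start_year")

    gpp8 = np.empty((n * 46, ny, nx))
    temp = np.empty((n * DAYS_PER_YEAR, ny, nx))
    precip = np.empty_like(temp)
    rad = np.empty_like(temp)
    truths = []
    for iy in range(ny):
        for ix in range(nx):
            series, clim, truth = generate_site_years(grid[iy, ix], preseason_window)
            gpp8[:, iy, ix] = aggregate_daily_to_8day(series.values).ravel()
            temp[:, iy, ix] = clim.temperature.ravel()
            precip[:, iy, ix] = clim.precipitation.ravel()
            rad[:, iy, ix] = clim.radiation.ravel()
            truth = truth.assign(y=iy, x=ix)
            truths.append(truth)

    years = y0 + np.arange(n)
    comp_doys = np.tile(8.0 * np.arange(46) + 1.0, n)
    comp_years = np.repeat(years, 46)
    time8 = dates_from_year_doy(comp_years, comp_doys.astype(int))
    gpp_ds = xr.Dataset(
        {"gpp": (("time", "y", "x"), gpp8)},
        coords={
            "time": ("time", time8),
            "year": ("time", comp_years),
            "composite": ("time", np.tile(np.arange(1, 47), n)),
            "y": np.arange(ny),
            "x": np.arange(nx),
        },
        attrs={"cadence": "8day", "calendar": "365_day (leap day dropped)"},
    )
    gpp_ds["gpp"].attrs["units"] = "g C m-2 day-1"

    day_years = np.repeat(years, DAYS_PER_YEAR)
    day_doys = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n)
    timed = dates_from_year_doy(day_years, day_doys)
    clim_ds = xr.Dataset(
        {
            "temperature": (("time", "y", "x"), temp),
            "precipitation": (("time", "y", "x"), precip),
            "radiation": (("time", "y", "x"), rad),
        },
        coords={
            "time": ("time", timed),
            "year": ("time", day_years),
            "doy": ("time", day_doys),
            "y": np.arange(ny),
            "x": np.arange(nx),
        },
        attrs={"cadence": "daily", "calendar": "365_day (leap day dropped)"},
    )
    clim_ds["temperature"].attrs["units"] = "degC"
    clim_ds["precipitation"].attrs["units"] = "mm day-1"
    clim_ds["radiation"].attrs["units"] = "W m-2"

    return gpp_ds, clim_ds, pd.concat(truths, ignore_index=True)
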