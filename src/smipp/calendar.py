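"""Fixed 365-day calendar helpers.

All series in this package live on a 365-day year (the leap day is dropped),
which keeps day-of-year (DOY) arithmetic exact and matches an 8-day-composite
world: 45 composites of 8 days plus a final composite of 5 days.
"""
from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365
N_COMPOSITES = 46

#: DOY range of meteorological summer (June-July-August) on the fixed calendar.
JJA_START_DOY = 152
JJA_END_DOY = 243

#: Length in days of each 8-day composite (1-based composite index k has
#: start DOY 8*(k-1)+1; the last composite covers only 5 days).
COMPOSITE_LENGTHS = np.array([8] * (N_COMPOSITES - 1) + [5])

#: Regression abscissa of each composite: start DOY + 3.5 (mid-point).
COMPOSITE_MID_DOYS = 8.0 * np.arange(N_COMPOSITES) + 1.0 + 3.5


def composite_slices() -> list[slice]:
    """0-based day slices of the 46 composites within a 365-day year."""
    starts = 8 * np.arange(N_COMPOSITES)
    return [slice(int(s), int(s + n)) for s, n in zip(starts, COMPOSITE_LENGTHS)]


def aggregate_daily_to_8day(daily: np.ndarray) -> np.ndarray:
    """Average daily values (..., 365) into 46 composites (..., 46).

    Composite k is the plain mean of its member days; the final composite
    averages 5 days.  NaNs propagate (a composite containing any missing day
    is missing).
    """
    daily = np.asarray(daily, dtype=float)
    if daily.shape[-1] != DAYS_PER_YEAR:
        raise ValueError(f"last axis must have {DAYS_PER_YEAR} days, got {daily.shape[-1]}")
    out = np.empty(daily.shape[:-1] + (N_COMPOSITES,), dtype=float)
    for k, sl in enumerate(composite_slices()):
        out[..., k] = daily[..., sl].mean(axis=-1)
    return out


def dates_from_year_doy(years: np.ndarray, doys: np.ndarray) -> np.ndarray:
    """Calendar dates (datetime64[D]) for (year, DOY) pairs on the 365-day grid.

    DOYs ≥ 60 in real leap years are shifted one day forward so the fixed
    calendar never lands on Feb 29.
    """
    years = np.asarray(years)
    doys = np.asarray(doys)
    base = np.array([f"{y}-01-01" for y in years], dtype="datetime64[D]")
    leap = (years % 4 == 0) & ((years % 100 != 0) | (years % 400 == 0))
    offset = doys - 1 + (leap & (doys >= 60)).astype(int)
    return base + offset.astype("timedelta64[D]")
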