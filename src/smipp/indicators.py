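"""Growing-season phenology and physiology indicators.

From each year's smoothed daily GPP curve three indicators are read off:

* ``gs_start`` — first day of year on which the (non-negative-clamped) curve
  is at or above the threshold;
* ``gs_end`` — last such day;
* ``gpp_max`` — the curve's peak value, with ``doy_of_max`` its (earliest) day.

The threshold is 10 % of the long-term mean ``gpp_max`` over all available
years of the pixel or site — one threshold per location, shared across its
years, so that phenology anomalies are measured against a fixed bar rather
than a bar that moves with each year's peak.

Crossings are reported at day resolution (first day at-or-above), without
sub-daily interpolation: the indicators are whole-day DOYs and interpolation
precision would sit far below their year-to-year noise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calendar import COMPOSITE_LENGTHS, DAYS_PER_YEAR, N_COMPOSITES
from .errors import InsufficientDataError
from .smoothing import SmoothedDailyCurve

__all__ = [
    "ThresholdSpec",
    "PhenologyRecord",
    "compute_threshold",
    "extract_indicators",
    "annual_gpp",
    "records_to_frame",
]

#: Peak search window for polynomial curves (degree-6 fits can diverge at the
#: year edges); SSA and raw curves search the whole year.
POLY_PEAK_WINDOW = (15, 350)


@dataclass(frozen=True)
class ThresholdSpec:
    """Growing-season threshold: ``threshold = fraction × reference`` where
    the reference is the long-term mean yearly ``gpp_max``."""

    fraction: float
    reference: float
    threshold: float


@dataclass
class PhenologyRecord:
    """One year's indicators.  ``valid`` is False when the curve never
    reaches the threshold or the peak falls outside the detected season."""

    year: int
    gs_start: float
    gpp_max: float
    doy_of_max: float
    gs_end: float
    annual_gpp: float
    valid: bool


def compute_threshold(gpp_max_by_year, fraction: float = 0.10) -> ThresholdSpec:
    """Threshold = ``fraction`` × mean of the yearly peak values (NaNs ignored)."""
    if not 0.0 < fraction < 1.0:
        raise InsufficientDataError(f"fraction must be in (0, 1), got {fraction}")
    vals = np.asarray(gpp_max_by_year, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InsufficientDataError("no valid yearly gpp_max values")
    ref = float(vals.mean())
    return ThresholdSpec(fraction, ref, fraction * ref)


def extract_indicators(
    curve: SmoothedDailyCurve,
    threshold: ThresholdSpec | float,
    peak_window: tuple[int, int] | None = None,
    annual: float | None = None,
    crossing_rule: str = "peak_run",
) -> PhenologyRecord:
    """Read the three indicators off one smoothed yearly curve.

    The curve is clamped at zero before any threshold logic.  The peak is
    searched within ``peak_window`` (defaults: DOY 15–350 for polynomial
    curves, whose tails can diverge, the whole year otherwise); ties go to
    the earliest day.

    Crossing rules:

    * ``"peak_run"`` (default) — ``gs_start`` / ``gs_end`` are the first and
      last DOYs of the contiguous at-or-above-threshold run that contains the
      peak.  Polynomial (and, less so, SSA) smoothers can ring at the year
      edges, producing spurious winter side lobes above the threshold; tying
      the season to the peak's own run ignores them.
    * ``"whole_year"`` — the literal first and last DOYs at or above the
      threshold anywhere in the year (a bimodal curve then spans both modes,
      and so does any above-threshold edge artefact).

    Years are flagged invalid — never raised — when the curve stays below the
    threshold or when the peak lands outside [gs_start, gs_end].

    ``annual`` is the year's annual GPP total computed from the *observed*
    series (see :func:`annual_gpp`); when omitted, the sum of the smoothed
    curve is used as a fallback.
    """
    thr = threshold.threshold if isinstance(threshold, ThresholdSpec) else float(threshold)
    if thr <= 0:
        raise InsufficientDataError("threshold must be positive")
    clamped = np.maximum(curve.values, 0.0)
    if peak_window is None:
        peak_window = POLY_PEAK_WINDOW if curve.method == "polynomial" else (1, DAYS_PER_YEAR)
    lo, hi = peak_window
    seg = clamped[lo - 1:hi]
    imax = int(np.argmax(seg))
    gpp_max = float(seg[imax])
    doy_of_max = float(lo + imax)
    annual = float(curve.values.sum()) if annual is None else float(annual)

    if crossing_rule not in ("peak_run", "whole_year"):
        raise InsufficientDataError(f"unknown crossing rule {crossing_rule!r}")
    mask = clamped >= thr
    year = curve.year if curve.year is not None else -1
    if not mask.any() or gpp_max <= thr:
        return PhenologyRecord(year, np.nan, gpp_max, doy_of_max, np.nan, annual, False)
    if crossing_rule == "whole_year":
        above = np.nonzero(mask)[0]
        i, j = int(above[0]), int(above[-1])
    else:
        pk = int(doy_of_max) - 1
        if not mask[pk]:
            return PhenologyRecord(year, np.nan, gpp_max, doy_of_max, np.nan, annual, False)
        i = j = pk
        while i > 0 and mask[i - 1]:
            i -= 1
        while j < DAYS_PER_YEAR - 1 and mask[j + 1]:
            j += 1
    gs_start, gs_end = float(i + 1), float(j + 1)
    valid = gs_start <= doy_of_max <= gs_end
    return PhenologyRecord(year, gs_start, gpp_max, doy_of_max, gs_end, annual, valid)


def annual_gpp(values: np.ndarray, cadence: str = "daily") -> float:
    """Annual GPP total (g C m⁻² yr⁻¹) from one year of daily or 8-day values.

    Daily: plain sum of the 365 values.  8-day: Σ valueₖ × daysₖ with 8 days
    per composite except 5 for the final one.  Any missing step makes the
    total NaN (callers decide how to treat incomplete years).
    """
    vals = np.asarray(values, dtype=float)
    if cadence == "daily":
        if vals.shape != (DAYS_PER_YEAR,):
            raise InsufficientDataError(f"daily year must have {DAYS_PER_YEAR} values")
        return float(vals.sum())
    if cadence == "8day":
        if vals.shape != (N_COMPOSITES,):
            raise InsufficientDataError(f"8-day year must have {N_COMPOSITES} composites")
        return float((vals * COMPOSITE_LENGTHS).sum())
    raise InsufficientDataError(f"unknown cadence {cadence!r}")


def records_to_frame(records) -> pd.DataFrame:
    """Stack PhenologyRecords into the standard indicator table."""
    return pd.DataFrame(
        [
            {
                "year": r.year,
                "gs_start": r.gs_start,
                "gpp_max": r.gpp_max,
                "doy_of_max": r.doy_of_max,
                "gs_end": r.gs_end,
                "annual_gpp": r.annual_gpp,
                "valid": r.valid,
            }
            for r in records
        ]
    )
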