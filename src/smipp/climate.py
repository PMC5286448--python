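"""Climate aggregation windows and indicator–climate sensitivity.

Phenology responds to the weather immediately before it happens: the
season-start and season-end indicators are therefore regressed on the mean
climate of the 30 days preceding their own *long-term mean* dates (the
"preseason"), with the window fixed across years so that year-specific
indicator noise cannot leak into the predictor.  The peak-GPP indicator is
regressed on summer (June–July–August) climate, since the seasonal peak
falls in JJA almost everywhere in the domain this emulates.

Sensitivity is reported as the Pearson correlation plus the OLS slope of the
indicator on the climate variable, both in raw calendar units (a larger
``gs_start`` is a *later* start); the "days earlier per °C" reading is a
reporting-time sign flip, applied nowhere in the numerics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calendar import DAYS_PER_YEAR, JJA_END_DOY, JJA_START_DOY
from .errors import InsufficientDataError

__all__ = [
    "SensitivityResult",
    "preseason_aggregate",
    "summer_aggregate",
    "sensitivity",
    "partial_correlation",
]


@dataclass
class SensitivityResult:
    """Pearson r, OLS slope (indicator units per climate unit), two-sided p,
    and sample size.  ``defined`` is False for a zero-variance climate series."""

    r: float
    slope: float
    p_value: float
    n: int
    defined: bool = True


def preseason_aggregate(
    daily: np.ndarray, mean_date: float, window: int = 30
) -> np.ndarray:
    """Per-year mean of a daily climate variable over the ``window`` days
    preceding ``mean_date``.

    ``daily`` has shape (n_years, 365).  The window covers DOYs
    [mean_date − window, mean_date − 1] (mean_date rounded to the nearest
    day).  When the window spills before DOY 1, the missing days are borrowed
    from the previous year's tail; the first year is then NaN.
    """
    daily = np.asarray(daily, dtype=float)
    if daily.ndim != 2 or daily.shape[1] != DAYS_PER_YEAR:
        raise InsufficientDataError(f"daily climate must have shape (n_years, {DAYS_PER_YEAR})")
    if window < 1:
        raise InsufficientDataError("window must be ≥ 1 day")
    end = int(round(mean_date))  # 1-based DOY, exclusive end of the window
    start = end - window
    n = daily.shape[0]
    out = np.full(n, np.nan)
    if start >= 1:
        out[:] = daily[:, start - 1:end - 1].mean(axis=1)
    else:
        # Borrow -start+1 days from the previous year's tail.
        n_prev = 1 - start
        for i in range(1, n):
            prev = daily[i - 1, DAYS_PER_YEAR - n_prev:]
            cur = daily[i, 0:end - 1]
            out[i] = np.concatenate([prev, cur]).mean()
    return out


def summer_aggregate(daily: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Per-year June–August aggregate of a daily climate variable.

    ``mode="mean"`` (temperature, radiation): plain mean over DOY 152–243.
    ``mode="monthly_total"`` (precipitation): the season total divided by 3,
    i.e. mean monthly precipitation in JJA.
    """
    daily = np.asarray(daily, dtype=float)
    if daily.ndim != 2 or daily.shape[1] != DAYS_PER_YEAR:
        raise InsufficientDataError(f"daily climate must have shape (n_years, {DAYS_PER_YEAR})")
    jja = daily[:, JJA_START_DOY - 1:JJA_END_DOY]
    if mode == "mean":
        return jja.mean(axis=1)
    if mode == "monthly_total":
        return jja.sum(axis=1) / 3.0
    raise InsufficientDataError(f"unknown summer aggregation mode {mode!r}")


def sensitivity(indicator, climate, min_years: int = 5) -> SensitivityResult:
    """Pearson r and OLS slope of a yearly indicator on a yearly climate series."""
    x = np.asarray(climate, dtype=float)
    y = np.asarray(indicator, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("indicator and climate series must align")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_years:
        raise InsufficientDataError(f"need ≥ {min_years} joint-finite years, got {int(ok.sum())}")
    x, y = x[ok], y[ok]
    if np.allclose(x, x[0]):
        return SensitivityResult(np.nan, np.nan, np.nan, int(ok.sum()), defined=False)
    res = stats.linregress(x, y)
    return SensitivityResult(
        float(res.rvalue), float(res.slope), float(res.pvalue), int(ok.sum())
    )


def partial_correlation(indicator, target_climate, control_climates) -> tuple[float, float]:
    """Partial Pearson correlation of an indicator with one climate variable,
    controlling for two others.

    Both the indicator and the target are residualised on the controls (with
    intercept) by least squares; the partial r is the plain correlation of
    the residuals, with a two-sided p from the t distribution on n − 4
    degrees of freedom (n years, two controls, intercept, target).
    """
    y = np.asarray(indicator, dtype=float)
    x = np.asarray(target_climate, dtype=float)
    Z = np.asarray(control_climates, dtype=float)
    if Z.ndim != 2:
        Z = Z.T if Z.ndim == 1 else Z
    if Z.shape[0] != y.size and Z.shape[1] == y.size:
        Z = Z.T
    if Z.shape != (y.size, 2):
        raise InsufficientDataError("need exactly two control series aligned with the data")
    ok = np.isfinite(y) & np.isfinite(x) & np.isfinite(Z).all(axis=1)
    if ok.sum() < 6:
        raise InsufficientDataError(f"need ≥ 6 joint-finite years, got {int(ok.sum())}")
    y, x, Z = y[ok], x[ok], Z[ok]
    n = y.size
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < 3:
        return np.nan, np.nan
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    if np.std(ry) == 0 or np.std(rx) == 0:
        return np.nan, np.nan
    r = float(stats.pearsonr(ry, rx).statistic)
    df = n - 4
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)
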