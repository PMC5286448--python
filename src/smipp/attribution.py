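"""Attribution of GPP trend and inter-annual variability to the indicators.

Once the anomaly regression has split each year's GPP anomaly into a
season-start, a peak and a season-end component, two questions remain:

* **Trend** — how much of the long-term trend of annual GPP does each
  component carry?  Each component series gets its own OLS trend
  (``Slope_start``, ``Slope_max``, ``Slope_end``); the relative contribution
  of component x is its slope's share of the total absolute slope,

      c_x = 100 · sign(Slope_x · Slope_GPP) · |Slope_x| / Σ|Slope|,

  positive when the component trends the same way as annual GPP.  The three
  absolute contributions sum to 100 % by construction.

* **Inter-annual variability (IAV)** — how much of the year-to-year
  fluctuation does each component carry?  Contributions are
  consistency-weighted: a component is credited in a given year when it has
  the same sign as that year's total reconstructed anomaly Ĝᵢ (the sum of
  the three components), weighted by the year's anomaly magnitude,

      c_x = 100 · Σᵢ component_x,i · sign(Ĝᵢ) / Σᵢ |Ĝᵢ|.

  The signed shares sum to exactly 100 %.  By default the reference anomaly
  is the reconstructed Ĝ (exact closure); the observed ΔGPP can be used
  instead, in which case closure is only approximate (the residual absorbs
  the rest).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "TrendResult",
    "ContributionResult",
    "ols_trend",
    "trend_contributions",
    "iav_contributions",
    "spatial_correlation",
]


@dataclass
class TrendResult:
    """OLS trend of a yearly series: slope per year, intercept at year 0,
    two-sided p-value on the slope, and the number of years used."""

    slope: float
    intercept: float
    p_value: float
    n_years: int


@dataclass
class ContributionResult:
    """Signed percentage contributions of the three components.

    ``mode`` is ``"trend"`` or ``"iav"``; ``defined`` is False when the
    contribution is undefined (all slopes zero, or zero total anomaly) —
    the shares are then NaN rather than an exception.
    """

    c_start: float
    c_max: float
    c_end: float
    mode: str
    defined: bool = True


def ols_trend(years, values) -> TrendResult:
    """Least-squares linear trend of ``values`` against calendar year."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(years) & np.isfinite(values)
    if ok.sum() < 3:
        raise InsufficientDataError(f"need ≥ 3 finite points, got {int(ok.sum())}")
    res = stats.linregress(years[ok], values[ok])
    # linregress returns NaN p for a perfectly constant y; treat as p=1.
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return TrendResult(float(res.slope), float(res.intercept), p, int(ok.sum()))


def trend_contributions(
    slope_start: float, slope_max: float, slope_end: float, gpp_trend: float
) -> ContributionResult:
    """Share of the annual-GPP trend carried by each component's trend.

    ``gpp_trend`` supplies only the sign against which agreement is judged.
    """
    slopes = np.array([slope_start, slope_max, slope_end], dtype=float)
    total = np.abs(slopes).sum()
    if total == 0.0:
        return ContributionResult(np.nan, np.nan, np.nan, "trend", defined=False)
    shares = 100.0 * np.sign(slopes * gpp_trend) * np.abs(slopes) / total
    return ContributionResult(*map(float, shares), "trend")


def iav_contributions(
    comp_start, comp_max, comp_end, reference=None
) -> ContributionResult:
    """Consistency-weighted IAV shares of the three component series.

    ``reference`` defaults to the reconstructed anomaly (the per-year sum of
    the three components), which guarantees the signed shares sum to exactly
    100.  Passing the observed ΔGPP series instead judges consistency against
    the observations; closure then holds only to the extent the regression
    residual is small.
    """
    comps = [np.asarray(c, dtype=float) for c in (comp_start, comp_max, comp_end)]
    n = comps[0].size
    if n < 3 or any(c.shape != (n,) for c in comps):
        raise InsufficientDataError("need ≥ 3 years of equal-length component series")
    ref = np.sum(comps, axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (n,):
        raise InsufficientDataError("reference series length mismatch")
    denom = np.abs(ref).sum()
    if denom == 0.0:
        return ContributionResult(np.nan, np.nan, np.nan, "iav", defined=False)
    s = np.sign(ref)
    shares = [100.0 * float((c * s).sum()) / denom for c in comps]
    return ContributionResult(*shares, "iav")


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray) -> tuple[float, float]:
    """Pearson R² and p between two co-registered maps, pixels as observations.

    NaN pixels are excluded pairwise; fewer than 10 jointly finite pixels is
    an error.
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.size != b.size:
        raise InsufficientDataError("maps must be co-registered (same size)")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 10:
        raise InsufficientDataError(f"need ≥ 10 joint-finite pixels, got {int(ok.sum())}")
    r, p = stats.pearsonr(a[ok], b[ok])
    return float(r**2), float(p)
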