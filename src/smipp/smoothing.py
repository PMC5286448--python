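"""Seasonal GPP curve smoothing.

Two smoothers, matching the two data cadences the pipeline handles:

* :func:`fit_seasonal_polynomial` — a sixth-degree polynomial in day of year,
  fitted by ordinary least squares to one year of 8-day composites.  This is
  the standard treatment for satellite-product seasonal cycles, where the 46
  composites are too coarse for spectral methods.
* :func:`ssa_smooth` — singular spectrum analysis (SSA) for daily series:
  embed the year in a Hankel trajectory matrix, take its SVD, and reconstruct
  from the leading eigentriples by anti-diagonal averaging.  Daily flux-tower
  GPP is noisy at the day scale; reconstructing from the four lowest-frequency
  components keeps the seasonal signal and discards the rest.

Numerical note: the polynomial predictor is DOY mapped affinely onto [-1, 1]
before powers are formed.  Raw DOY⁶ reaches ~2×10¹⁵ and destroys the
conditioning of the normal equations; in the scaled basis the design is
benign.  Coefficients are stored in the scaled basis with the transform
recorded on the curve object.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel, svd

from .calendar import DAYS_PER_YEAR
from .errors import InsufficientDataError

__all__ = [
    "PolynomialCurve",
    "SmoothedDailyCurve",
    "fit_seasonal_polynomial",
    "evaluate_curve",
    "ssa_smooth",
]

#: Fraction of a year that may be missing before the year is unusable.
MAX_MISSING_FRACTION = 0.20

DEFAULT_SSA_WINDOW = 120
DEFAULT_SSA_COMPONENTS = 4


@dataclass
class PolynomialCurve:
    """A fitted degree-d polynomial in (optionally rescaled) day of year.

    ``coefficients`` are lowest-order first.  When ``domain`` is ``(lo, hi)``
    the polynomial argument is ``t = 2*(doy - lo)/(hi - lo) - 1``; when
    ``domain`` is ``None`` the argument is the raw DOY.  ``resid_std`` is the
    RMS of the fit residuals (the ε of the seasonal regression).
    """

    coefficients: np.ndarray
    domain: tuple[float, float] | None = (1.0, float(DAYS_PER_YEAR))
    year: int | None = None
    resid_std: float = 0.0

    def __call__(self, doy: np.ndarray) -> np.ndarray:
        doy = np.asarray(doy, dtype=float)
        if self.domain is not None:
            lo, hi = self.domain
            t = 2.0 * (doy - lo) / (hi - lo) - 1.0
        else:
            t = doy
        # Horner evaluation, highest order first.
        out = np.zeros_like(t)
        for c in self.coefficients[::-1]:
            out = out * t + c
        return out


@dataclass
class SmoothedDailyCurve:
    """365 smoothed daily GPP values for one year.

    Negative values are retained here; they are clamped to zero only at the
    indicator-extraction stage, so the stored curve remains the faithful fit.
    """

    values: np.ndarray
    method: str  # "polynomial" | "ssa" | "raw"
    year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (DAYS_PER_YEAR,):
            raise InsufficientDataError(
                f"smoothed curve must have {DAYS_PER_YEAR} values, got {self.values.shape}"
            )


def fit_seasonal_polynomial(
    values: np.ndarray,
    doys: np.ndarray,
    degree: int = 6,
    year: int | None = None,
) -> PolynomialCurve:
    """OLS fit of a degree-``degree`` polynomial in DOY to one year's composites.

    ``values`` are the 8-day GPP composites (NaN = missing), ``doys`` their
    mid-point day-of-year abscissae (strictly increasing).  Missing composites
    are omitted from the design; more than 20 % missing, or fewer than
    ``degree + 1`` points, is an error.
    """
    values = np.asarray(values, dtype=float)
    doys = np.asarray(doys, dtype=float)
    if values.shape != doys.shape or values.ndim != 1:
        raise InsufficientDataError("values and doys must be 1-D and equally long")
    if np.any(np.diff(doys) <= 0):
        raise InsufficientDataError("composite DOYs must be strictly increasing")
    ok = np.isfinite(values)
    if ok.size and (1.0 - ok.mean()) > MAX_MISSING_FRACTION:
        raise InsufficientDataError(
            f"{(~ok).sum()}/{ok.size} composites missing exceeds "
            f"{MAX_MISSING_FRACTION:.0%} tolerance"
        )
    if ok.sum() < degree + 1:
        raise InsufficientDataError(
            f"need at least {degree + 1} composites, got {int(ok.sum())}"
        )
    lo, hi = 1.0, float(DAYS_PER_YEAR)
    t = 2.0 * (doys[ok] - lo) / (hi - lo) - 1.0
    design = np.vander(t, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(design, values[ok], rcond=None)
    if rank < degree + 1:
        raise InsufficientDataError("rank-deficient polynomial design")
    resid = values[ok] - design @ coef
    return PolynomialCurve(coef, (lo, hi), year, float(np.sqrt(np.mean(resid**2))))


def evaluate_curve(curve: PolynomialCurve) -> SmoothedDailyCurve:
    """Evaluate a fitted polynomial at DOY 1..365."""
    doy = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)
    return SmoothedDailyCurve(curve(doy), "polynomial", curve.year)


def _fill_gaps(x: np.ndarray) -> np.ndarray:
    """Linear interpolation over interior NaNs; edges held at nearest value."""
    ok = np.isfinite(x)
    if ok.all():
        return x
    idx = np.arange(x.size)
    return np.interp(idx, idx[ok], x[ok])


def ssa_smooth(
    daily: np.ndarray,
    window: int = DEFAULT_SSA_WINDOW,
    n_components: int = DEFAULT_SSA_COMPONENTS,
    year: int | None = None,
) -> SmoothedDailyCurve:
    """Smooth one year of daily GPP by singular spectrum analysis.

    Builds the ``window × (N - window + 1)`` Hankel trajectory matrix of the
    series, takes its singular value decomposition, keeps the ``n_components``
    leading eigentriples (eigentriples counted singly, not in paired groups),
    and reconstructs a series of the same length by averaging the retained
    matrix over its anti-diagonals.  The reconstruction is invariant to the
    sign ambiguity of individual singular vectors.

    Missing days (NaN) are linearly interpolated before embedding; more than
    20 % missing is an error.
    """
    x = np.asarray(daily, dtype=float).copy()
    if x.ndim != 1:
        raise InsufficientDataError("daily series must be 1-D")
    n = x.size
    if not 2 <= window <= n:
        raise InsufficientDataError(f"embedding window must be in [2, {n}], got {window}")
    if not 1 <= n_components <= window:
        raise InsufficientDataError("n_components must be in [1, window]")
    ok = np.isfinite(x)
    if not ok.any():
        raise InsufficientDataError("all days missing")
    if (1.0 - ok.mean()) > MAX_MISSING_FRACTION:
        raise InsufficientDataError(
            f"{(~ok).sum()}/{n} days missing exceeds {MAX_MISSING_FRACTION:.0%} tolerance"
        )
    x = _fill_gaps(x)

    K = n - window + 1
    traj = hankel(x[:window], x[window - 1:])
    U, s, Vt = svd(traj, full_matrices=False)
    k = min(n_components, s.size)
    rank_k = (U[:, :k] * s[:k]) @ Vt[:k]

    rec = np.zeros(n)
    cnt = np.zeros(n)
    for i in range(window):
        rec[i:i + K] += rank_k[i]
        cnt[i:i + K] += 1.0
    return SmoothedDailyCurve(rec / cnt, "ssa", year)
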