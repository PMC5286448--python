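"""The SMIPP anomaly regression.

The Statistical Model of Integrated Phenology and Physiology (SMIPP)
expresses annual GPP as a function of three indicators — growing-season
start, peak daily GPP, growing-season end — and linearises it about the
long-term means.  Writing Δ for a year's departure from the record mean,

    ΔGPP ≈ η_start · ΔGS_start + η_max · ΔGPP_max + η_end · ΔGS_end

where the η are the sensitivities of annual GPP to each indicator.  Sign
convention: ΔGS_start is counted **positive when the season starts earlier**
(advance) and ΔGS_end **positive when it ends later** (delay), so that, in
the common phenological regime, all three sensitivities come out positive
and directly comparable.

The sensitivities are estimated per pixel/site by ordinary least squares on
the yearly anomaly table; the fitted model then splits each year's GPP
anomaly into three additive indicator-driven components (plus an OLS
residual), which downstream attribution converts into trend and
inter-annual-variability contributions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError

__all__ = [
    "AnomalyTable",
    "SmippFit",
    "build_anomalies",
    "check_independence",
    "fit_smipp",
    "decompose",
]

PREDICTORS = ("d_gs_start", "d_gpp_max", "d_gs_end")

#: Fewest usable years accepted for a fit: 4 parameters need at least one
#: residual degree of freedom.
MIN_YEARS = 5


@dataclass
class AnomalyTable:
    """Per-year signed anomalies, columns ``d_gpp``, ``d_gs_start``,
    ``d_gpp_max``, ``d_gs_end`` indexed by year.  Each column sums to zero
    (anomalies about the record mean over the years retained)."""

    data: pd.DataFrame
    means: pd.Series  # long-term means the anomalies are taken about

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SmippFit:
    """Fitted sensitivities and the decomposition they imply.

    ``components`` has one column per indicator (η·Δ per year) and the OLS
    ``residual``; ``intercept + components + residual`` reproduces ``d_gpp``
    exactly, year by year.
    """

    eta_start: float
    eta_max: float
    eta_end: float
    intercept: float
    r_squared: float
    p_values: dict[str, float]
    components: pd.DataFrame
    n_years: int
    predictor_correlation_flag: bool = False


def build_anomalies(records: pd.DataFrame, min_years: int = MIN_YEARS) -> AnomalyTable:
    """Anomaly table from an indicator table (columns ``year``, ``gs_start``,
    ``gpp_max``, ``gs_end``, ``annual_gpp``, optional ``valid``).

    Years flagged invalid, or with any missing value, are dropped listwise.
    Signs: ΔGS_start = mean − value (advance positive); ΔGS_end = value −
    mean (delay positive); ΔGPP_max and ΔGPP are plain departures.
    """
    df = records.copy()
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    cols = ["gs_start", "gpp_max", "gs_end", "annual_gpp"]
    df = df.dropna(subset=cols)
    if len(df) < min_years:
        raise InsufficientDataError(
            f"need at least {min_years} usable years, got {len(df)}"
        )
    means = df[cols].mean()
    table = pd.DataFrame(
        {
            "d_gpp": (df["annual_gpp"] - means["annual_gpp"]).to_numpy(),
            "d_gs_start": (means["gs_start"] - df["gs_start"]).to_numpy(),
            "d_gpp_max": (df["gpp_max"] - means["gpp_max"]).to_numpy(),
            "d_gs_end": (df["gs_end"] - means["gs_end"]).to_numpy(),
        },
        index=pd.Index(df["year"].astype(int).to_numpy(), name="year"),
    )
    return AnomalyTable(table, means)


def check_independence(table: AnomalyTable) -> pd.DataFrame:
    """Pairwise R² (and p) among the three predictors.

    The linearised model assumes the indicators vary independently; this
    reports how far a given record deviates from that.  Correlation is
    reported, never corrected for.
    """
    rows = []
    for a, b in combinations(PREDICTORS, 2):
        x, y = table.data[a].to_numpy(), table.data[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"pair": f"{a}~{b}", "r_squared": r**2, "p_value": p})
    return pd.DataFrame(rows)


def fit_smipp(
    table: AnomalyTable,
    intercept: bool = True,
    min_years: int = MIN_YEARS,
    correlation_alpha: float = 0.05,
) -> SmippFit:
    """Estimate (η_start, η_max, η_end) by OLS of ΔGPP on the three anomalies.

    The intercept is retained even though mean-centred anomalies force it to
    ≈ 0 — it protects the decomposition identity when years were dropped
    after centring.  Raises :class:`DegenerateDesignError`, naming the
    offending predictor, when a predictor has zero variance or the design is
    rank deficient.
    """
    df = table.data
    if len(df) < min_years:
        raise InsufficientDataError(f"need at least {min_years} years, got {len(df)}")
    for name in PREDICTORS:
        if np.allclose(df[name].to_numpy(), df[name].iloc[0]):
            raise DegenerateDesignError(f"predictor {name} has zero variance")
    X = df[list(PREDICTORS)].to_numpy()
    if intercept:
        X = sm.add_constant(X, prepend=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("rank-deficient anomaly design matrix")
    res = sm.OLS(df["d_gpp"].to_numpy(), X).fit()
    params = res.params if intercept else np.concatenate([[0.0], res.params])
    pvals = res.pvalues if intercept else np.concatenate([[np.nan], res.pvalues])
    c0, etas = params[0], params[1:]

    comp = pd.DataFrame(
        {
            "start": etas[0] * df["d_gs_start"],
            "max": etas[1] * df["d_gpp_max"],
            "end": etas[2] * df["d_gs_end"],
        },
        index=df.index,
    )
    comp["residual"] = df["d_gpp"] - c0 - comp[["start", "max", "end"]].sum(axis=1)

    indep = check_independence(table)
    flag = bool((indep["p_value"] < correlation_alpha).any())
    return SmippFit(
        eta_start=float(etas[0]),
        eta_max=float(etas[1]),
        eta_end=float(etas[2]),
        intercept=float(c0),
        r_squared=float(res.rsquared),
        p_values={
            "start": float(pvals[1]),
            "max": float(pvals[2]),
            "end": float(pvals[3]),
        },
        components=comp,
        n_years=len(df),
        predictor_correlation_flag=flag,
    )


def decompose(fit: SmippFit, table: AnomalyTable) -> pd.DataFrame:
    """Per-year decomposition: the three η·Δ components and the residual.

    Recomputed from the fitted sensitivities and the table (rather than read
    off the fit) so the identity ΔGPP = intercept + Σ components + residual
    holds for whatever table is supplied.
    """
    df = table.data
    out = pd.DataFrame(
        {
            "start": fit.eta_start * df["d_gs_start"],
            "max": fit.eta_max * df["d_gpp_max"],
            "end": fit.eta_end * df["d_gs_end"],
        },
        index=df.index,
    )
    out["residual"] = df["d_gpp"] - fit.intercept - out.sum(axis=1)
    return out
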