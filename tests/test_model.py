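"""Anomaly construction and the sensitivity regression."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smipp import (
    AnomalyTable,
    DegenerateDesignError,
    InsufficientDataError,
    build_anomalies,
    check_independence,
    decompose,
    fit_smipp,
)


def records_from_anomalies(ds, dm, de, dg, years=None):
    n = len(ds)
    years = np.arange(2000, 2000 + n) if years is None else years
    return pd.DataFrame(
        {
            "year": years,
            "gs_start": 120.0 - np.asarray(ds),
            "gpp_max": 8.0 + np.asarray(dm),
            "gs_end": 280.0 + np.asarray(de),
            "annual_gpp": 900.0 + np.asarray(dg),
        }
    )


def synthetic_table(rng, n=15, eta=(3.0, 96.0, 2.5), noise=0.0):
    ds = rng.normal(0, 5, n)
    dm = rng.normal(0, 0.5, n)
    de = rng.normal(0, 5, n)
    dg = eta[0] * ds + eta[1] * dm + eta[2] * de + noise * rng.normal(size=n)
    return build_anomalies(records_from_anomalies(ds, dm, de, dg))


class TestBuildAnomalies:
    def test_sign_conventions(self):
        rec = pd.DataFrame(
            {
                "year": [2000, 2001, 2002],
                "gs_start": [100, 110, 120],
                "gpp_max": [8, 10, 12],
                "gs_end": [285, 295, 290],
                "annual_gpp": [800, 900, 1000],
            }
        )
        table = build_anomalies(rec, min_years=3)
        assert table.data["d_gs_start"].tolist() == [10, 0, -10]   # advance positive
        assert table.data["d_gs_end"].tolist() == [-5, 5, 0]       # delay positive
        assert table.data["d_gpp_max"].tolist() == [-2, 0, 2]

    def test_columns_center_to_zero(self, rng):
        table = synthetic_table(rng)
        assert table.data.sum().to_numpy() == pytest.approx(0.0, abs=1e-9)

    def test_invalid_years_dropped_listwise(self, rng):
        rec = records_from_anomalies(*(rng.normal(size=8) for _ in range(4)))
        rec["valid"] = [True] * 6 + [False, False]
        table = build_anomalies(rec)
        assert len(table) == 6

    def test_too_few_years_rejected(self, rng):
        rec = records_from_anomalies(*(rng.normal(size=4) for _ in range(4)))
        with pytest.raises(InsufficientDataError):
            build_anomalies(rec)


class TestIndependenceCheck:
    def test_identical_predictors_have_unit_r2(self, rng):
        ds = rng.normal(size=10)
        table = build_anomalies(records_from_anomalies(ds, -ds, rng.normal(size=10),
                                                       rng.normal(size=10)))
        out = check_independence(table).set_index("pair")
        assert out.loc["d_gs_start~d_gpp_max", "r_squared"] == pytest.approx(1.0)

    def test_orthogonal_predictors_have_zero_r2(self):
        ds = np.array([1.0, -1.0, 1.0, -1.0, 0.0, 0.0])
        dm = np.array([0.0, 0.0, 0.0, 0.0, 1.0, -1.0])
        table = build_anomalies(records_from_anomalies(ds, dm, ds + dm, ds - dm),
                                min_years=5)
        out = check_independence(table).set_index("pair")
        assert out.loc["d_gs_start~d_gpp_max", "r_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_independent_columns_have_small_r2_at_large_n(self, rng):
        cols = [rng.normal(size=1000) for _ in range(4)]
        table = build_anomalies(records_from_anomalies(*cols,
                                                       years=np.arange(1000)))
        assert (check_independence(table)["r_squared"] < 0.01).all()


class TestFit:
    def test_exact_linear_system_recovered(self, rng):
        table = synthetic_table(rng, eta=(3.0, 96.0, 2.5), noise=0.0)
        fit = fit_smipp(table)
        assert fit.eta_start == pytest.approx(3.0, abs=1e-8)
        assert fit.eta_max == pytest.approx(96.0, abs=1e-8)
        assert fit.eta_end == pytest.approx(2.5, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_identity(self, rng):
        table = synthetic_table(rng, noise=20.0)
        fit = fit_smipp(table)
        lhs = fit.intercept + fit.components[["start", "max", "end"]].sum(axis=1) \
            + fit.components["residual"]
        scale = np.abs(table.data["d_gpp"]).max()
        assert lhs.to_numpy() == pytest.approx(table.data["d_gpp"].to_numpy(),
                                               abs=1e-9 * scale)

    def test_scaling_response_scales_coefficients(self, rng):
        table = synthetic_table(rng, noise=10.0)
        fit1 = fit_smipp(table)
        scaled = AnomalyTable(table.data.assign(d_gpp=3.0 * table.data["d_gpp"]),
                              table.means)
        fit3 = fit_smipp(scaled)
        assert fit3.eta_max == pytest.approx(3.0 * fit1.eta_max, rel=1e-9)
        assert fit3.components["max"].to_numpy() == pytest.approx(
            3.0 * fit1.components["max"].to_numpy(), rel=1e-9
        )

    def test_zero_variance_predictor_named(self, rng):
        ds = np.zeros(10)
        table = build_anomalies(
            records_from_anomalies(ds, rng.normal(size=10), rng.normal(size=10),
                                   rng.normal(size=10))
        )
        with pytest.raises(DegenerateDesignError, match="d_gs_start"):
            fit_smipp(table)

    def test_pvalues_calibrated_under_null(self, rng):
        # ΔGPP independent of the predictors: coefficient p-values should be
        # uniform; check with a KS test over repeated draws.
        pvals = []
        for _ in range(300):
            table = synthetic_table(rng, eta=(0.0, 0.0, 0.0), noise=30.0)
            pvals.append(fit_smipp(table).p_values["max"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.03)

    def test_no_intercept_variant_keeps_identity(self, rng):
        table = synthetic_table(rng, noise=15.0)
        fit = fit_smipp(table, intercept=False)
        assert fit.intercept == 0.0
        lhs = fit.components[["start", "max", "end"]].sum(axis=1) \
            + fit.components["residual"]
        assert lhs.to_numpy() == pytest.approx(table.data["d_gpp"].to_numpy())


class TestDecompose:
    def test_perfect_fit_has_zero_residual(self, rng):
        table = synthetic_table(rng, noise=0.0)
        fit = fit_smipp(table)
        out = decompose(fit, table)
        assert out["residual"].to_numpy() == pytest.approx(0.0, abs=1e-8)

    def test_residuals_sum_to_zero_with_intercept(self, rng):
        table = synthetic_table(rng, noise=25.0)
        out = decompose(fit_smipp(table), table)
        assert out["residual"].sum() == pytest.approx(0.0, abs=1e-8)

    def test_zero_coefficient_zero_component(self, rng):
        ds = rng.normal(0, 5, 12)
        dm = rng.normal(0, 0.5, 12)
        de = rng.normal(0, 5, 12)
        dg = 96.0 * dm  # no start/end influence
        table = build_anomalies(records_from_anomalies(ds, dm, de, dg))
        fit = fit_smipp(table)
        out = decompose(fit, table)
        assert out["start"].to_numpy() == pytest.approx(0.0, abs=1e-6)
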