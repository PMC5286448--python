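"""Climate window aggregation and sensitivity/partial-correlation statistics."""
import numpy as np
import pytest

from smipp import (
    InsufficientDataError,
    partial_correlation,
    preseason_aggregate,
    sensitivity,
    summer_aggregate,
)


def daily_grid(fn, n_years=6):
    doy = np.arange(1, 366, dtype=float)
    return np.tile(fn(doy), (n_years, 1))


class TestPreseasonAggregate:
    def test_constant_temperature(self):
        out = preseason_aggregate(np.full((5, 365), 10.0), mean_date=120)
        assert out == pytest.approx(10.0)

    def test_linear_ramp_mean_at_window_midpoint(self):
        out = preseason_aggregate(daily_grid(lambda d: d), mean_date=120, window=30)
        assert out == pytest.approx(104.5)  # mean of DOY 90..119

    def test_matches_direct_summation_oracle(self, rng):
        daily = rng.normal(size=(8, 365))
        out = preseason_aggregate(daily, mean_date=200, window=30)
        assert out == pytest.approx(daily[:, 169:199].mean(axis=1))

    def test_window_borrows_from_previous_year(self, rng):
        daily = rng.normal(size=(4, 365))
        out = preseason_aggregate(daily, mean_date=20, window=30)
        assert np.isnan(out[0])  # first year has no previous December
        expected = np.concatenate([daily[0, -11:], daily[1, :19]]).mean()
        assert out[1] == pytest.approx(expected)

    def test_bad_window_rejected(self):
        with pytest.raises(InsufficientDataError):
            preseason_aggregate(np.ones((3, 365)), mean_date=120, window=0)


class TestSummerAggregate:
    def test_constant_radiation(self):
        assert summer_aggregate(np.full((4, 365), 200.0)) == pytest.approx(200.0)

    def test_sinusoid_matches_integral_oracle(self):
        f = lambda d: 10 + 5 * np.sin(2 * np.pi * (d - 105) / 365)
        out = summer_aggregate(daily_grid(f))
        doy = np.arange(152, 244, dtype=float)
        assert out == pytest.approx(f(doy).mean(), rel=1e-12)

    def test_zero_precipitation(self):
        assert summer_aggregate(np.zeros((3, 365)), mode="monthly_total") == pytest.approx(0.0)

    def test_monthly_total_is_season_total_over_three(self, rng):
        daily = rng.gamma(1.0, 2.0, size=(5, 365))
        out = summer_aggregate(daily, mode="monthly_total")
        assert out == pytest.approx(daily[:, 151:243].sum(axis=1) / 3.0)


class TestSensitivity:
    def test_exact_linear_relation(self, rng):
        temp = rng.normal(10, 2, 20)
        res = sensitivity(-1.9 * temp + 100.0, temp)
        assert res.r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-1.9)

    def test_independent_series_weak_correlation(self, rng):
        res = sensitivity(rng.normal(size=500), rng.normal(size=500))
        assert abs(res.r) < 0.1

    def test_affine_climate_rescaling(self, rng):
        temp = rng.normal(10, 2, 30)
        ind = -1.9 * temp + rng.normal(0, 1, 30)
        base = sensitivity(ind, temp)
        scaled = sensitivity(ind, 2.0 * temp + 5.0)
        assert scaled.slope == pytest.approx(base.slope / 2.0)
        assert scaled.r == pytest.approx(base.r)

    def test_zero_variance_climate_flagged(self):
        res = sensitivity(np.arange(10.0), np.full(10, 3.0))
        assert not res.defined and np.isnan(res.slope)

    def test_nan_years_excluded_pairwise(self, rng):
        temp = rng.normal(size=12)
        ind = 2.0 * temp
        ind[3] = np.nan
        res = sensitivity(ind, temp)
        assert res.n == 11
        assert res.slope == pytest.approx(2.0)


class TestPartialCorrelation:
    def test_matches_residual_regression_oracle(self, rng):
        for _ in range(100):
            n = 30
            Z = rng.normal(size=(n, 2))
            x = Z @ [0.5, -0.2] + rng.normal(size=n)
            y = 0.8 * x + Z @ [0.3, 0.4] + rng.normal(size=n)
            r, _ = partial_correlation(y, x, Z)
            D = np.column_stack([np.ones(n), Z])
            ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
            rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
            expected = np.corrcoef(ry, rx)[0, 1]
            assert r == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 40
        Z = rng.normal(size=(n, 2))
        x = rng.normal(size=n) + Z[:, 0]
        y = 0.5 * x + rng.normal(size=n)
        r, p = partial_correlation(y, x, Z)
        df = pd.DataFrame({"y": y, "x": x, "z1": Z[:, 0], "z2": Z[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_indicator_explained_by_control_gives_zero(self, rng):
        n = 50
        Z = rng.normal(size=(n, 2))
        y = 3.0 * Z[:, 0] + 1e-9 * rng.normal(size=n)
        x = rng.normal(size=n)
        r, _ = partial_correlation(y, x, Z)
        assert abs(r) < 0.3  # residualisation removes essentially everything

    def test_reduces_to_plain_r_with_independent_controls(self, rng):
        # Population argument: controls unrelated to x and y leave the
        # correlation unchanged up to sampling error.
        n = 2000
        Z = rng.normal(size=(n, 2))
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        r_partial, _ = partial_correlation(y, x, Z)
        r_plain = np.corrcoef(x, y)[0, 1]
        assert r_partial == pytest.approx(r_plain, abs=0.05)

    def test_too_few_years_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            partial_correlation(np.ones(5), np.ones(5), np.ones((5, 2)))
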