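"""Polynomial and SSA smoothers: exactness, linearity, noise rejection."""
import numpy as np
import pytest

from smipp import (
    InsufficientDataError,
    PolynomialCurve,
    evaluate_curve,
    fit_seasonal_polynomial,
    generate_seasonal_curve,
    ssa_smooth,
)
from smipp.calendar import COMPOSITE_MID_DOYS, aggregate_daily_to_8day

DOY = np.arange(1, 366, dtype=float)


def _poly_values(coef, doys):
    # Independent oracle: numpy polynomial evaluation in the scaled basis.
    t = 2.0 * (doys - 1.0) / 364.0 - 1.0
    return np.polynomial.polynomial.polyval(t, coef)


class TestPolynomialFit:
    def test_exactly_representable_signal_recovered(self, rng):
        coef = rng.normal(size=7)
        values = _poly_values(coef, COMPOSITE_MID_DOYS)
        fit = fit_seasonal_polynomial(values, COMPOSITE_MID_DOYS)
        assert fit.coefficients == pytest.approx(coef, abs=1e-8)
        assert fit.resid_std == pytest.approx(0.0, abs=1e-9)

    def test_constant_series(self):
        fit = fit_seasonal_polynomial(np.full(46, 5.0), COMPOSITE_MID_DOYS)
        assert fit.coefficients[0] == pytest.approx(5.0, abs=1e-9)
        assert fit.coefficients[1:] == pytest.approx(0.0, abs=1e-8)

    def test_linearity_in_the_data(self, rng):
        values = rng.normal(5, 2, 46)
        a = fit_seasonal_polynomial(values, COMPOSITE_MID_DOYS).coefficients
        b = fit_seasonal_polynomial(3.0 * values, COMPOSITE_MID_DOYS).coefficients
        assert b == pytest.approx(3.0 * a, rel=1e-9)

    def test_idempotent_on_own_fixed_point(self, rng):
        # Sampling a degree-6 curve at the composite abscissae and refitting
        # must reproduce it exactly.
        coef = rng.normal(size=7)
        curve = evaluate_curve(PolynomialCurve(coef))
        sampled = PolynomialCurve(coef)(COMPOSITE_MID_DOYS)
        refit = fit_seasonal_polynomial(sampled, COMPOSITE_MID_DOYS)
        assert evaluate_curve(refit).values == pytest.approx(curve.values, abs=1e-8)

    def test_bump_fit_matches_normal_equations_oracle(self):
        # Independent oracle: solve the degree-6 least-squares problem by
        # forming the normal equations directly on the same composites.
        daily = generate_seasonal_curve(120, 280, 10)
        comp = aggregate_daily_to_8day(daily)
        curve = evaluate_curve(fit_seasonal_polynomial(comp, COMPOSITE_MID_DOYS))
        t = 2.0 * (COMPOSITE_MID_DOYS - 1.0) / 364.0 - 1.0
        V = np.vander(t, 7, increasing=True)
        coef = np.linalg.solve(V.T @ V, V.T @ comp)
        oracle = _poly_values(coef, DOY)
        assert curve.values == pytest.approx(oracle, abs=1e-8)
        assert abs(curve.values.argmax() + 1 - 200) <= 8  # symmetric peak kept

    def test_missing_composites_tolerated_up_to_limit(self, rng):
        coef = rng.normal(size=7)
        values = _poly_values(coef, COMPOSITE_MID_DOYS)
        values[::7] = np.nan  # 7/46 ≈ 15% missing
        fit = fit_seasonal_polynomial(values, COMPOSITE_MID_DOYS)
        assert fit.coefficients == pytest.approx(coef, abs=1e-8)
        values[::4] = np.nan  # > 20%
        with pytest.raises(InsufficientDataError):
            fit_seasonal_polynomial(values, COMPOSITE_MID_DOYS)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_seasonal_polynomial(np.ones(5), np.arange(5, dtype=float) + 1)

    def test_non_increasing_doys_rejected(self):
        doys = COMPOSITE_MID_DOYS.copy()
        doys[10] = doys[9]
        with pytest.raises(InsufficientDataError):
            fit_seasonal_polynomial(np.ones(46), doys)


class TestEvaluateCurve:
    def test_constant_polynomial(self):
        curve = evaluate_curve(PolynomialCurve(np.array([2.0, 0, 0, 0, 0, 0, 0])))
        assert curve.values == pytest.approx(2.0)

    def test_identity_in_raw_doy_basis(self):
        curve = evaluate_curve(PolynomialCurve(np.array([0.0, 1.0]), domain=None))
        assert curve.values[99] == pytest.approx(100.0)

    def test_matches_independent_polynomial_oracle(self, rng):
        for _ in range(10):
            coef = rng.normal(size=7)
            got = evaluate_curve(PolynomialCurve(coef)).values
            assert got == pytest.approx(_poly_values(coef, DOY), abs=1e-10)


class TestSSA:
    def test_constant_signal_reproduced(self):
        rec = ssa_smooth(np.full(365, 3.0), window=120, n_components=4)
        assert rec.values == pytest.approx(3.0, abs=1e-9)

    def test_annual_sinusoid_inside_four_components(self):
        x = 5 + 4 * np.sin(2 * np.pi * DOY / 365)
        rec = ssa_smooth(x)
        assert np.sqrt(np.mean((rec.values - x) ** 2)) < 1e-6

    def test_low_hankel_rank_signal_exact(self):
        # Two sinusoids span Hankel rank 4: reconstruction must be exact.
        x = 3 * np.sin(2 * np.pi * DOY / 365) + np.cos(2 * np.pi * 2 * DOY / 365)
        rec = ssa_smooth(x, n_components=4)
        assert rec.values == pytest.approx(x, abs=1e-8)

    def test_denoises_sinusoid_in_most_trials(self):
        clean = 5 + 4 * np.sin(2 * np.pi * DOY / 365)
        wins = 0
        n_trials = 200
        master = np.random.default_rng(77)
        for _ in range(n_trials):
            noisy = clean + master.normal(0, 0.5, 365)
            rec = ssa_smooth(noisy).values
            if np.mean((rec - clean) ** 2) < np.mean((noisy - clean) ** 2):
                wins += 1
        assert wins >= 0.95 * n_trials

    def test_gap_filling_and_missing_limit(self):
        x = 5 + 4 * np.sin(2 * np.pi * DOY / 365)
        gappy = x.copy()
        gappy[50:80] = np.nan  # ~8% missing
        rec = ssa_smooth(gappy)
        assert np.sqrt(np.mean((rec.values - x) ** 2)) < 0.05
        gappy[100:200] = np.nan  # > 20%
        with pytest.raises(InsufficientDataError):
            ssa_smooth(gappy)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InsufficientDataError):
            ssa_smooth(np.full(365, np.nan))
        with pytest.raises(InsufficientDataError):
            ssa_smooth(np.ones(365), window=1)
        with pytest.raises(InsufficientDataError):
            ssa_smooth(np.ones(365), window=10, n_components=11)
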