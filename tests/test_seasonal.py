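"""Sinusoid fitting, series classification and extreme extraction."""

import math

import numpy as np
import pytest

from paleoseason.io import read_samples
from paleoseason.seasonal import (
    DegenerateSeriesError,
    InsufficientDataError,
    SinusoidFit,
    SinusoidRegressor,
    classify_series,
    extract_extremes,
    fit_sinusoid,
)

from conftest import TWO_PI, make_series, sinusoid_series


def grid_search_oracle(x, y, lam_grid, phi_grid):
    """Dense grid search over (lam, phi) with exact linear solves for (M, A).

    Independent of the package's fitting path: no joint refinement, no
    quadrature reparametrization.
    """
    best = (np.inf, None)
    for lam in lam_grid:
        for phi in phi_grid:
            design = np.column_stack([np.ones_like(x), np.sin(TWO_PI * x / lam + phi)])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            ssr = float(np.sum((y - design @ coef) ** 2))
            if ssr < best[0]:
                best = (ssr, (abs(coef[1]), coef[0], lam, phi))
    return best[1]


class TestFitSinusoid:
    def test_exact_recovery_noise_free(self):
        series = sinusoid_series(A=1.0, M=0.0, lam=30.0, n=15, span=45.0)
        fit = fit_sinusoid(series)
        assert fit.converged
        assert fit.A == pytest.approx(1.0, abs=1e-6)
        assert fit.M == pytest.approx(0.0, abs=1e-6)
        assert fit.lam == pytest.approx(30.0, abs=1e-6)

    def test_noisy_recovery_matches_grid_oracle(self):
        rng = np.random.default_rng(7)
        series = sinusoid_series(A=1.0, M=0.0, lam=30.0, n=15, span=45.0, noise_sd=0.2, rng=rng)
        fit = fit_sinusoid(series)
        assert abs(fit.A - 1.0) < 0.15
        x, y = series.positions, series.values
        oracle_A, oracle_M, _, _ = grid_search_oracle(
            x, y, np.linspace(20.0, 45.0, 120), np.linspace(0, TWO_PI, 90, endpoint=False)
        )
        assert fit.A == pytest.approx(oracle_A, abs=0.05)
        assert fit.M == pytest.approx(oracle_M, abs=0.05)

    def test_constant_series_not_converged(self):
        series = make_series(np.arange(6.0), np.full(6, -6.0))
        fit = fit_sinusoid(series)
        assert not fit.converged
        assert fit.A == pytest.approx(0.0)
        assert classify_series(fit, series) == "non_sinusoidal"

    def test_too_few_points(self):
        series = make_series([0.0, 1.0, 2.0], [1.0, 2.0, 1.0])
        with pytest.raises(InsufficientDataError):
            fit_sinusoid(series)

    def test_degenerate_positions(self):
        est = SinusoidRegressor()
        with pytest.raises(DegenerateSeriesError):
            est.fit(np.zeros((6, 1)), np.arange(6.0))

    def test_position_shift_only_changes_phase(self):
        rng = np.random.default_rng(3)
        base = sinusoid_series(A=1.5, M=-6.0, lam=28.0, n=16, span=40.0, noise_sd=0.1, rng=rng)
        shifted = make_series(base.positions + 100.0, base.values)
        f0, f1 = fit_sinusoid(base), fit_sinusoid(shifted)
        assert f1.A == pytest.approx(f0.A, abs=1e-6)
        assert f1.M == pytest.approx(f0.M, abs=1e-6)
        assert f1.lam == pytest.approx(f0.lam, rel=1e-6)

    def test_fixed_wavelength_honoured(self):
        series = sinusoid_series(A=1.0, lam=30.0, n=20, span=60.0)
        fit = fit_sinusoid(series, init={"wavelength": 30.0})
        assert fit.lam == 30.0
        assert fit.A == pytest.approx(1.0, abs=1e-8)

    def test_amplitude_error_monotone_in_noise(self):
        lam, A = 30.0, 1.0
        medians = []
        for noise in (0.05, 0.2, 0.6):
            errs = []
            for rep in range(20):
                rng = np.random.default_rng(1000 + rep)
                s = sinusoid_series(A=A, lam=lam, n=15, span=45.0, noise_sd=noise, rng=rng)
                errs.append(abs(fit_sinusoid(s).A - A))
            medians.append(np.median(errs))
        assert medians[0] <= medians[1] * 1.05
        assert medians[1] <= medians[2] * 1.05

    def test_sklearn_param_interface(self):
        est = SinusoidRegressor(wavelength=25.0)
        assert est.get_params()["wavelength"] == 25.0
        est.set_params(wavelength=None, n_wavelengths=50)
        series = sinusoid_series(A=1.0, lam=30.0, n=20, span=60.0)
        est.fit(series.positions.reshape(-1, 1), series.values)
        pred = est.predict(series.positions.reshape(-1, 1))
        assert np.allclose(pred, series.values, atol=1e-6)


class TestClassify:
    def test_clear_amplitude_is_sinusoidal(self):
        fit = SinusoidFit(A=2.0, M=0.0, lam=30.0, phi=0.0, resid_sd=0.2, converged=True, A_span=2.0)
        assert classify_series(fit, None) == "sinusoidal"

    def test_amplitude_below_noise_threshold(self):
        fit = SinusoidFit(A=0.1, M=0.0, lam=30.0, phi=0.0, resid_sd=0.3, converged=True, A_span=0.1)
        assert classify_series(fit, None) == "non_sinusoidal"

    def test_threshold_configurable(self):
        fit = SinusoidFit(A=0.5, M=0.0, lam=30.0, phi=0.0, resid_sd=0.3, converged=True, A_span=0.5)
        assert classify_series(fit, None, k=1.0) == "sinusoidal"
        assert classify_series(fit, None, k=2.0) == "non_sinusoidal"

    def test_flat_noisy_series_excluded(self):
        rng = np.random.default_rng(11)
        series = make_series(np.linspace(0, 36, 14), -6.0 + 0.2 * rng.standard_normal(14))
        fit = fit_sinusoid(series)
        assert classify_series(fit, series) == "non_sinusoidal"


class TestExtractExtremes:
    def test_full_cycle_fitted_extremes(self):
        series = sinusoid_series(A=1.0, M=-6.0, lam=30.0, n=20, span=30.0)
        fit = fit_sinusoid(series)
        est = extract_extremes(series, fit, method="fitted")
        assert est.completeness == "both_extremes"
        assert est.summer_peak == pytest.approx(-5.0, abs=1e-6)
        assert est.winter_trough == pytest.approx(-7.0, abs=1e-6)
        assert est.mean_annual == pytest.approx(-6.0, abs=1e-6)
        assert est.seasonality == pytest.approx(2.0, abs=1e-6)

    def test_fitted_extremes_satisfy_model_identities(self):
        rng = np.random.default_rng(5)
        series = sinusoid_series(A=1.3, M=-5.5, lam=30.0, n=20, span=36.0, noise_sd=0.15, rng=rng)
        fit = fit_sinusoid(series)
        est = extract_extremes(series, fit, method="fitted")
        assert est.summer_peak - est.winter_trough == pytest.approx(2 * fit.A)
        assert est.mean_annual == pytest.approx(fit.M)

    def test_half_cycle_trough_only(self):
        # span covers the trough (at x=22.5 for phi=0, lam=30) but not a peak
        series = sinusoid_series(A=1.0, M=-6.0, lam=30.0, n=10, span=13.0, x0=16.0)
        fit = fit_sinusoid(series, init={"wavelength": 30.0})
        est = extract_extremes(series, fit, method="fitted")
        assert est.completeness == "trough_only"
        assert est.winter_trough is not None and est.summer_peak is None
        assert est.mean_annual is None

    def test_observed_picks_measured_samples(self):
        rng = np.random.default_rng(9)
        series = sinusoid_series(A=1.0, M=-6.0, lam=30.0, n=16, span=30.0, noise_sd=0.2, rng=rng)
        fit = fit_sinusoid(series)
        est = extract_extremes(series, fit, method="observed")
        assert est.summer_peak in series.values
        assert est.winter_trough in series.values

    def test_multi_cycle_single_most_extreme_pair(self):
        series = sinusoid_series(A=1.0, M=-6.0, lam=30.0, n=40, span=60.0)
        fit = fit_sinusoid(series)
        est = extract_extremes(series, fit, method="observed")
        assert est.completeness == "both_extremes"
        assert est.summer_peak == pytest.approx(series.values.max())
        assert est.winter_trough == pytest.approx(series.values.min())

    def test_unknown_method_rejected(self):
        series = sinusoid_series()
        fit = fit_sinusoid(series)
        with pytest.raises(ValueError):
            extract_extremes(series, fit, method="visual")

    def test_synthetic_cohort_extremes_near_generator_truth(self, paper_like_tables, enamel_csv):
        """Raw extracted extremes track the dense noise-free damped signal.

        The oracle is a brute-force min/max of the densely evaluated
        generator signal (truth-table parameters + closed-form damping).
        """
        scenario, tables = paper_like_tables
        truth = tables["truth"].set_index("tooth_id")
        series_list = read_samples(enamel_csv, "enamel_o")
        model_f = scenario.damping_model().f
        checked = 0
        observed_errs = []
        for series in series_list:
            t = truth.loc[series.tooth_id]
            if t.non_sinusoidal:
                continue
            fit = fit_sinusoid(series)
            # dense damped truth via closed-form attenuation of the generator sinusoid
            xs = np.linspace(series.positions[0], series.positions[-1], 4000)
            dense = t.M_enamel_true + t.A_enamel_true * model_f * np.sin(
                TWO_PI * xs / t.wavelength_mm + t.phase
            )
            fitted = extract_extremes(series, fit, method="fitted")
            if fitted.completeness == "both_extremes":
                # the smoothed-curve extremes average out analytical noise
                assert fitted.summer_peak == pytest.approx(dense.max(), abs=0.3)
                assert fitted.winter_trough == pytest.approx(dense.min(), abs=0.3)
                checked += 1
            observed = extract_extremes(series, fit, method="observed")
            if observed.completeness == "both_extremes":
                # observed extremes carry one sample's analytical noise (sd 0.2)
                assert observed.summer_peak == pytest.approx(
                    dense.max(), abs=3 * scenario.noise_sd
                )
                assert observed.winter_trough == pytest.approx(
                    dense.min(), abs=3 * scenario.noise_sd
                )
                observed_errs += [
                    observed.summer_peak - dense.max(),
                    observed.winter_trough - dense.min(),
                ]
        assert checked >= 10
        assert np.median(np.abs(observed_errs)) < scenario.noise_sd
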