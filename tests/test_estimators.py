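"""Tests of the calibration, time-constant, viscosity, AI and shear estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import coflowmetry as cf
from coflowmetry.exceptions import (
    DomainError,
    FitFailureError,
    InsufficientDataError,
    SteadyWindowNotFoundError,
    UndefinedAIError,
)
from coflowmetry.units import CP

PRINTED_POINTS = [
    cf.CalibrationPoint(0.05, 0.153),
    cf.CalibrationPoint(0.25, 0.442),
    cf.CalibrationPoint(0.5, 0.609),
    cf.CalibrationPoint(3.0, 0.893),
]


class TestCalibrateAlpha:
    def test_printed_points_recover_reference_line(self):
        # OLS oracle on the inverted points; the bench line was
        # 0.3038 beta + 0.7935 (fitted there on more repeats)
        model = cf.calibrate_alpha(PRINTED_POINTS, 3e-3, 1e-3)
        assert model.intercept == pytest.approx(0.78502293, abs=1e-6)
        assert model.slope == pytest.approx(0.32359307, abs=1e-6)
        assert model.r_squared > 0.9

    def test_exact_recovery_from_linear_alpha(self, alpha):
        # synthesize beta points lying exactly on a known correction line
        betas = np.array([0.2, 0.4, 0.6, 0.8])
        ratios = [float(alpha(b)) * b / (1 - b) / 3.0 for b in betas]
        pts = [cf.CalibrationPoint(r, b) for r, b in zip(ratios, betas)]
        model = cf.calibrate_alpha(pts, 3e-3, 1e-3)
        assert model.slope == pytest.approx(alpha.slope, abs=1e-12)
        assert model.intercept == pytest.approx(alpha.intercept, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            cf.calibrate_alpha([PRINTED_POINTS[0]], 3e-3, 1e-3)


class TestLambdaSeries:
    def test_constant_lambda_recovered_from_logistic_decay(self, logistic_trace):
        series = cf.estimate_lambda_series(logistic_trace, cf.UNIT_ALPHA)
        sel = series.defined & (series.beta > 0.05)
        assert np.all(np.abs(series.lam[sel] - 5.0) / 5.0 < 0.002)

    def test_flat_trace_fully_masked(self):
        t = np.arange(10) * 0.5
        trace = cf.InterfaceTrace(t, np.full(10, 0.4), np.array(["off"] * 10))
        series = cf.estimate_lambda_series(trace, cf.DEFAULT_ALPHA)
        assert not np.any(series.defined)

    def test_linear_lambda_profile_recovered_pointwise(self, glycerin_offphase, alpha):
        lam = cf.TimeConstantProfile(8.8902, -7.6899)
        series = cf.estimate_lambda_series(glycerin_offphase, alpha)
        sel = series.defined & (series.beta >= 0.3) & (series.beta <= 0.7)
        rel = np.abs(series.lam[sel] - lam(series.beta[sel])) / lam(series.beta[sel])
        assert np.max(rel) < 0.01

    def test_on_phase_samples_rejected(self, glycerin_run):
        trace, _ = glycerin_run
        with pytest.raises(DomainError):
            cf.estimate_lambda_series(trace, cf.DEFAULT_ALPHA)


class TestSummarizeLambda:
    def test_exact_linear_series(self):
        beta = np.linspace(0.3, 0.7, 20)
        lam = -7.0 * beta + 9.0
        series = cf.LambdaSeries(np.arange(20.0), beta, lam)
        summ = cf.summarize_lambda(series)
        assert summ.slope == pytest.approx(-7.0, abs=1e-10)
        assert summ.mean == pytest.approx(lam.mean(), abs=1e-12)
        assert summ.r_squared == pytest.approx(1.0)

    def test_constant_series(self):
        beta = np.linspace(0.35, 0.65, 10)
        series = cf.LambdaSeries(np.arange(10.0), beta, np.full(10, 4.2))
        summ = cf.summarize_lambda(series)
        assert summ.slope == pytest.approx(0.0, abs=1e-9)
        assert summ.mean == pytest.approx(4.2)

    def test_too_few_samples_in_window(self):
        series = cf.LambdaSeries(np.arange(5.0), np.full(5, 0.9), np.full(5, 3.0))
        with pytest.raises(InsufficientDataError):
            cf.summarize_lambda(series, (0.3, 0.7))

    def test_glycerin_window_summaries(self, glycerin_offphase, alpha):
        summ = cf.summarize_lambda(cf.estimate_lambda_series(glycerin_offphase, alpha))
        assert summ.slope == pytest.approx(-7.6899, rel=0.02)
        # generating-line values over the same window samples
        assert 4.5 < summ.mean < 6.0


class TestPrevMethodFit:
    def test_exact_parameter_recovery(self):
        t = np.arange(0, 60, 0.5)
        y = 2.0 * np.exp(-t / 4.0) + 1.4
        beta = 1.0 - 1.0 / y
        trace = cf.InterfaceTrace(t, beta, np.array(["off"] * t.size))
        fit = cf.fit_lambda_prev(trace)
        assert fit.a1 == pytest.approx(2.0, abs=1e-6)
        assert fit.a2 == pytest.approx(1.4, abs=1e-6)
        assert fit.lambda_pm == pytest.approx(4.0, abs=1e-6)

    def test_unit_correction_logistic_is_exactly_exponential(self, logistic_trace):
        # with alpha_R == 1 the decay of 1/(1-beta) is a pure exponential,
        # so the previous method is exact there
        fit = cf.fit_lambda_prev(logistic_trace)
        assert fit.lambda_pm == pytest.approx(5.0, rel=1e-6)

    def test_calibrated_correction_breaks_constant_lambda_model(self, alpha):
        # with a beta-dependent correction the relaxation is not a single
        # exponential: the constant-lambda fit converges but is biased,
        # which is why the pointwise estimator is preferred
        lam = cf.TimeConstantProfile(5.0)
        t, b = cf.integrate_interface(0.7, 0.0, lam, alpha, 60.0, 0.5)
        trace = cf.InterfaceTrace(t, b, np.array(["off"] * len(t)))
        fit = cf.fit_lambda_prev(trace)
        assert np.isfinite(fit.lambda_pm) and fit.lambda_pm > 0
        assert abs(fit.lambda_pm - 5.0) > 0.05

    def test_flat_trace_unidentifiable(self):
        t = np.arange(0, 10, 0.5)
        trace = cf.InterfaceTrace(t, np.full(t.size, 0.5), np.array(["off"] * t.size))
        with pytest.raises(FitFailureError):
            cf.fit_lambda_prev(trace)


class TestViscositySteady:
    def test_glycerin_program_pooled_viscosity(self, glycerin_run, alpha):
        trace, _ = glycerin_run
        res = cf.viscosity_steady(trace, cf.DEFAULT_FLOWS, 1e-3, alpha)
        assert res.mean / CP == pytest.approx(2.977, rel=1e-6)
        assert res.period_mean.size == 4

    def test_constant_trace_at_fixed_point_returns_exact_viscosity(self, alpha):
        flows = cf.DEFAULT_FLOWS
        mu_star = 2.4e-3
        b = cf.steady_interface(mu_star, 1e-3, flows.Q_t0, flows.Q_r, alpha)
        t = np.arange(0, 480, 0.5)
        phase = np.array([flows.phase_at(x) for x in t])
        trace = cf.InterfaceTrace(t, np.full(t.size, b), phase)
        res = cf.viscosity_steady(trace, flows, 1e-3, alpha)
        assert res.mean == pytest.approx(mu_star, rel=1e-12)

    def test_large_compliance_has_no_steady_window(self, alpha, geometry):
        # a heavily compliant circuit (lambda ~ 2000 s) never flattens
        lam0 = cf.lambda_from_compliance(
            geometry, 2.977e-3, cf.ComplianceModel(C_base=2e-9)
        )
        scen = cf.ScenarioPreset(
            label="bigC", mu_t=2.977e-3, lam=cf.TimeConstantProfile(lam0)
        )
        trace, _ = cf.make_trace(scen, beta0=0.4, n_periods=2)
        with pytest.raises(SteadyWindowNotFoundError):
            cf.viscosity_steady(trace, cf.DEFAULT_FLOWS, 1e-3, alpha)

    def test_simulation_roundtrip_is_identity_on_viscosity(self, alpha):
        # steady_interface -> simulate -> viscosity_steady recovers mu_t
        for mu_t in (1.5e-3, 4e-3):
            scen = cf.ScenarioPreset(
                label="x", mu_t=mu_t, lam=cf.TimeConstantProfile(3.0)
            )
            trace, _ = cf.make_trace(scen, n_periods=1)
            res = cf.viscosity_steady(trace, cf.DEFAULT_FLOWS, 1e-3, alpha)
            assert res.mean == pytest.approx(mu_t, rel=1e-6)


class TestAggregationIndex:
    def _trace(self, t, I):
        return cf.IntensityTrace(times=t, intensity=I)

    def test_linear_decay_gives_half(self):
        t = np.linspace(240, 480, 100)
        I = np.interp(t, [240, 480], [120, 80])
        res = cf.aggregation_index(self._trace(t, I), (240, 480))
        assert res.AI == pytest.approx(0.5, abs=1e-12)

    def test_fast_exponential_decay_approaches_one(self):
        t = np.linspace(0, 240, 481)
        tau = 5.0
        I = 80 + 40 * np.exp(-t / tau)
        res = cf.aggregation_index(self._trace(t, I), (0, 240))
        # closed form: AI -> 1 - tau/W for tau << W
        assert res.AI == pytest.approx(1 - tau / 240.0, abs=5e-3)

    def test_instant_drop_gives_one(self):
        t = np.linspace(0, 10, 50)
        I = np.where(t == 0, 100.0, 20.0)
        res = cf.aggregation_index(self._trace(t, I), (0, 10))
        assert res.AI == pytest.approx(1.0, abs=0.05)

    def test_flat_intensity_undefined(self):
        t = np.linspace(0, 10, 20)
        with pytest.raises(UndefinedAIError):
            cf.aggregation_index(self._trace(t, np.full(20, 7.0)), (0, 10))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0),
           shift=st.floats(0.0, 1000.0))
    def test_affine_and_time_shift_invariance(self, a, b, shift):
        t = np.linspace(0, 240, 200)
        I = 80 + 40 * np.exp(-t / 30.0)
        ref = cf.aggregation_index(self._trace(t, I), (0, 240)).AI
        out = cf.aggregation_index(self._trace(t + shift, a * I + b),
                                   (shift, 240 + shift)).AI
        assert out == pytest.approx(ref, rel=1e-9)


class TestShearRateAndPowerLaw:
    def test_worked_example_hct50(self, geometry):
        g = cf.shear_rate(1e-6 / 3600.0, 0.829, geometry)
        assert g == pytest.approx(804.18, rel=1e-3)
        assert 200 <= g <= 900  # the steady-flow shear range of the instrument

    def test_zero_flow_and_beta_scaling(self, geometry):
        assert cf.shear_rate(0.0, 0.5, geometry) == 0.0
        g1 = cf.shear_rate(1e-10, 0.8, geometry)
        assert cf.shear_rate(1e-10, 0.4, geometry) == pytest.approx(2 * g1)

    def test_power_law_exact_recovery(self):
        g = np.array([100.0, 300.0, 600.0, 900.0])
        mu = 50e-3 * g ** (0.7 - 1.0)
        fit = cf.fit_power_law(g, mu)
        assert fit.mu0 == pytest.approx(50e-3, rel=1e-10)
        assert fit.n == pytest.approx(0.7, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_newtonian_limit_and_two_point_interpolation(self):
        g = np.array([100.0, 400.0, 800.0])
        fit = cf.fit_power_law(g, np.full(3, 3e-3))
        assert fit.n == pytest.approx(1.0, abs=1e-12)
        fit2 = cf.fit_power_law([100.0, 900.0], [5e-3, 2e-3])
        assert fit2.r_squared == pytest.approx(1.0)

    def test_flow_rate_from_velocity_unit_conversion(self, geometry):
        # 5.556 mm/s over a 1 mm x 50 um duct is 1 mL/h
        q = cf.flow_rate_from_velocity(1e-6 / 3600.0 / (1e-3 * 50e-6), geometry)
        assert q == pytest.approx(1e-6 / 3600.0, rel=1e-12)
        assert cf.flow_rate_from_velocity(0.0, geometry) == 0.0


class TestSegmentPeriods:
    def _trace(self, duration, flows):
        t = np.arange(0, duration, flows.sampling_dt)
        phase = np.array([flows.phase_at(x) for x in t])
        return cf.InterfaceTrace(t, np.full(t.size, 0.5), phase)

    def test_whole_and_partial_periods(self):
        flows = cf.DEFAULT_FLOWS
        assert len(cf.segment_periods(self._trace(4 * 480, flows), flows)) == 4
        assert len(cf.segment_periods(self._trace(4.5 * 480, flows), flows)) == 4

    def test_short_trace_rejected(self):
        flows = cf.DEFAULT_FLOWS
        with pytest.raises(InsufficientDataError):
            cf.segment_periods(self._trace(0.5 * 480, flows), flows)

    def test_phase_split_is_clean(self):
        flows = cf.DEFAULT_FLOWS
        for on, off in cf.segment_periods(self._trace(2 * 480, flows), flows):
            assert np.all(on.phase == "on")
            assert np.all(off.phase == "off")
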