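"""Forward-model contracts: closed forms vs ODE oracle, continuity, AUC, peaks."""

import numpy as np
import pytest

from pbftpk.models import (
    AbsorptionSchedule,
    BatemanModel,
    ConcentrationTimeSeries,
    InputStage,
    OneCompartmentDisposition,
    PBFTPKModel,
    TwoCompartmentDisposition,
    auc_infinity_analytic,
    bateman_concentration,
    cmax_tmax,
    concentration_one_compartment,
    concentration_two_compartment,
)

from .conftest import ode_concentration, random_pbftpk, slowest_constant


class TestDomainTypes:
    def test_series_rejects_nonincreasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            ConcentrationTimeSeries(times=[0.0, 1.0, 1.0], concentrations=[0, 1, 2])

    def test_series_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ConcentrationTimeSeries(times=[0.0, 1.0], concentrations=[0.0])

    def test_series_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            ConcentrationTimeSeries(times=[0.0, 1.0], concentrations=[0.0, -1.0])

    def test_stage_amount_is_rate_times_duration(self):
        assert InputStage(duration=2.5, rate=0.4).amount == 2.5 * 0.4

    def test_stage_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            InputStage(duration=0.0, rate=1.0)

    def test_schedule_breakpoints_and_total(self, theodur_schedule):
        np.testing.assert_allclose(theodur_schedule.breakpoints, [4.2, 7.4, 11.6])
        assert theodur_schedule.total_duration == pytest.approx(11.6, abs=1e-12)

    def test_schedule_needs_a_stage(self):
        with pytest.raises(ValueError):
            AbsorptionSchedule([])

    def test_two_compartment_hybrid_ordering(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            disp = TwoCompartmentDisposition(*rng.uniform(0.01, 3.0, size=3))
            alpha, beta = disp.hybrid_constants
            assert alpha > beta > 0

    def test_bateman_rejects_equal_rate_constants(self):
        with pytest.raises(ValueError, match="degenerate"):
            BatemanModel(ka=0.5, kel=0.5, scale=1.0)


class TestOneCompartment:
    def test_unit_case_frozen_values(self, unit_one_stage_model):
        # during input: C(tau) = (r/kel)(1 - e^{-kel tau}); after: exponential decay
        m = unit_one_stage_model
        assert m.concentration(1.0) == pytest.approx(0.63212, abs=5e-6)
        assert m.concentration(2.0) == pytest.approx(0.23254, abs=5e-6)

    def test_zero_at_dose_time(self, unit_one_stage_model, theodur_schedule):
        assert unit_one_stage_model.concentration(0.0) == 0.0
        c = concentration_one_compartment(
            theodur_schedule, OneCompartmentDisposition(0.0866), 0.0
        )
        assert c == 0.0

    def test_negative_time_rejected(self, unit_one_stage_model):
        with pytest.raises(ValueError, match="egative"):
            unit_one_stage_model.concentration(-0.1)

    def test_continuity_at_breakpoints(self, theodur_schedule):
        disp = OneCompartmentDisposition(0.0866)
        for b in theodur_schedule.breakpoints:
            lo = concentration_one_compartment(theodur_schedule, disp, b - 1e-9)
            hi = concentration_one_compartment(theodur_schedule, disp, b + 1e-9)
            assert hi == pytest.approx(lo, rel=1e-6)

    def test_terminal_phase_is_pure_exponential(self, theodur_schedule):
        disp = OneCompartmentDisposition(0.0866)
        tau = theodur_schedule.total_duration
        c_tau = concentration_one_compartment(theodur_schedule, disp, tau)
        for dt in (1.0, 5.0, 20.0):
            expected = c_tau * np.exp(-disp.kel * dt)
            got = concentration_one_compartment(theodur_schedule, disp, tau + dt)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_superposition_equal_rates_merge(self):
        # two stages with equal rates == one stage of the combined duration
        merged = AbsorptionSchedule([InputStage(5.0, 0.7)])
        split = AbsorptionSchedule([InputStage(2.0, 0.7), InputStage(3.0, 0.7)])
        disp = OneCompartmentDisposition(0.3)
        t = np.linspace(0.0, 20.0, 200)
        np.testing.assert_allclose(
            concentration_one_compartment(split, disp, t),
            concentration_one_compartment(merged, disp, t),
            rtol=1e-12,
        )

    def test_matches_ode_oracle_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            model = random_pbftpk(rng, two_compartment=False)
            horizon = 3 * model.schedule.total_duration + 5 / slowest_constant(model)
            t = np.linspace(0.0, horizon, 50)
            closed = model.concentration(t)
            oracle = ode_concentration(model, t)
            np.testing.assert_allclose(
                closed, oracle, rtol=1e-6, atol=1e-9 * closed.max()
            )


class TestTwoCompartment:
    def test_zero_at_dose_time(self):
        sched = AbsorptionSchedule([InputStage(2.0, 1.0)])
        disp = TwoCompartmentDisposition(0.5, 0.3, 0.2)
        assert concentration_two_compartment(sched, disp, 0.0) == 0.0

    def test_decoupled_peripheral_reduces_to_one_compartment(self):
        sched = AbsorptionSchedule([InputStage(1.5, 0.8), InputStage(2.0, 0.2)])
        disp2 = TwoCompartmentDisposition(k12=1e-12, k21=0.3, k10=0.25)
        disp1 = OneCompartmentDisposition(kel=0.25)
        t = np.linspace(0.0, 15.0, 120)
        np.testing.assert_allclose(
            concentration_two_compartment(sched, disp2, t),
            concentration_one_compartment(sched, disp1, t),
            atol=1e-9,
        )

    def test_single_stage_matches_ode_oracle(self):
        sched = AbsorptionSchedule([InputStage(2.0, 1.0)])
        disp = TwoCompartmentDisposition(k12=0.5, k21=0.3, k10=0.2)
        model = PBFTPKModel(sched, disp)
        t = np.array([0.5, 1.0, 2.0, 3.0, 5.0, 10.0, 20.0])
        np.testing.assert_allclose(
            model.concentration(t), ode_concentration(model, t), rtol=1e-7
        )

    def test_matches_ode_oracle_random_draws(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            model = random_pbftpk(rng, two_compartment=True)
            horizon = 3 * model.schedule.total_duration + 5 / slowest_constant(model)
            t = np.linspace(0.0, horizon, 50)
            closed = model.concentration(t)
            oracle = ode_concentration(model, t)
            np.testing.assert_allclose(
                closed, oracle, rtol=1e-6, atol=1e-9 * closed.max()
            )

    def test_terminal_decay_governed_by_beta(self):
        sched = AbsorptionSchedule([InputStage(1.0, 1.0)])
        disp = TwoCompartmentDisposition(0.6, 0.2, 0.3)
        _, beta = disp.hybrid_constants
        t1, t2 = 40.0, 50.0
        c1 = concentration_two_compartment(sched, disp, t1)
        c2 = concentration_two_compartment(sched, disp, t2)
        assert np.log(c1 / c2) / (t2 - t1) == pytest.approx(beta, rel=1e-3)


class TestBateman:
    def test_zero_at_dose_time(self):
        assert bateman_concentration(BatemanModel(2.0, 0.5, 1.0), 0.0) == 0.0

    def test_peak_location_closed_form(self):
        m = BatemanModel(ka=2.0, kel=0.5, scale=1.0)
        assert m.tmax == pytest.approx(0.92420, abs=5e-6)
        # grid confirmation: no grid value exceeds the value at tmax
        t = np.linspace(0.0, 10.0, 5001)
        assert bateman_concentration(m, m.tmax) >= bateman_concentration(m, t).max() - 1e-12

    def test_value_at_peak_matches_ode_oracle(self):
        # first-order absorption compartment integrated numerically
        from scipy.integrate import solve_ivp

        ka, kel, scale = 2.0, 0.5, 1.0
        m = BatemanModel(ka, kel, scale)

        def rhs(_t, y):
            gut, c = y
            return [-ka * gut, ka * gut - kel * c]

        sol = solve_ivp(rhs, (0.0, m.tmax), [scale, 0.0], rtol=1e-11, atol=1e-14)
        assert bateman_concentration(m, m.tmax) == pytest.approx(
            sol.y[1, -1], rel=1e-8
        )


class TestAucAndPeak:
    def test_auc_unit_case(self, unit_one_stage_model):
        assert auc_infinity_analytic(unit_one_stage_model) == pytest.approx(1.0)

    def test_auc_theodur_like(self, theodur_schedule):
        model = PBFTPKModel(theodur_schedule, OneCompartmentDisposition(0.1))
        assert auc_infinity_analytic(model) == pytest.approx(0.1818, abs=5e-5)

    def test_auc_two_compartment(self):
        sched = AbsorptionSchedule([InputStage(2.0, 0.5)])  # total amount 1
        model = PBFTPKModel(sched, TwoCompartmentDisposition(0.7, 0.4, 0.5))
        assert auc_infinity_analytic(model) == pytest.approx(2.0)

    def test_auc_conservation_numerical(self):
        rng = np.random.default_rng(5)
        for two in (False, True):
            model = random_pbftpk(rng, two_compartment=two)
            horizon = model.schedule.total_duration + 30.0 / slowest_constant(model)
            t = np.linspace(0.0, horizon, 20001)
            numeric = np.trapezoid(model.concentration(t), t)
            assert numeric == pytest.approx(auc_infinity_analytic(model), rel=1e-3)

    def test_tmax_single_stage_is_absorption_end(self, unit_one_stage_model):
        cmax, tmax = cmax_tmax(unit_one_stage_model)
        assert tmax == 1.0
        assert cmax == pytest.approx(1.0 - np.exp(-1.0))

    def test_tmax_second_stage_zero_rate(self):
        sched = AbsorptionSchedule([InputStage(1.0, 1.0), InputStage(2.0, 0.0)])
        model = PBFTPKModel(sched, OneCompartmentDisposition(1.0))
        cmax, tmax = cmax_tmax(model)
        assert tmax == pytest.approx(1.0, abs=1e-6)
        assert cmax == pytest.approx(1.0 - np.exp(-1.0), rel=1e-9)

    def test_tmax_two_compartment_matches_grid_oracle(self):
        sched = AbsorptionSchedule([InputStage(2.0, 1.0)])
        model = PBFTPKModel(sched, TwoCompartmentDisposition(0.5, 0.3, 0.2))
        cmax, tmax = cmax_tmax(model)
        t = np.linspace(0.0, 30.0, 300001)
        c = model.concentration(t)
        assert cmax >= c.max() - 1e-10
        assert tmax == pytest.approx(t[np.argmax(c)], abs=1e-3)
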