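"""RK4 engine: oracle equivalence, linearity, mass balance, exposure metrics."""

import math
from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mipdkit as mk
from mipdkit.simulate import _make_plan, _rk4_maps, _run_plan, _run_plan_loop


def params1(cl=4.58, v1=107.1):
    return mk.IndividualParameters(cl_L_h=cl, v1_L=v1)


def params2(cl=18.0, v1=38.0, q=60.0, v2=73.0):
    return mk.IndividualParameters(cl_L_h=cl, v1_L=v1, q_L_h=q, v2_L=v2)


def regimen(md=1000.0, interval=12.0, n=4, inf_min=60.0, drug="drug"):
    return mk.build_regimen(drug, md, interval, n, mk.EPOCH, inf_min)


class TestRK4:
    def test_no_events_zero_state_stays_zero(self):
        tc = mk.rk4_solve(params1(), [], horizon_h=12.0, start=mk.EPOCH)
        assert np.all(tc.central_conc_mg_L == 0.0)

    def test_matches_one_compartment_closed_form(self):
        p = params1()
        tc = mk.rk4_solve(p, regimen(), horizon_h=48.0)
        exact = mk.closed_form_one_compartment(p, regimen(), tc.times_h)
        diff = np.abs(tc.central_conc_mg_L - exact)
        assert np.max(diff) < 1e-3
        assert np.median(diff) <= 0.0007203

    def test_doubling_doses_doubles_concentrations(self):
        p = params2()
        tc1 = mk.rk4_solve(p, regimen(md=500), horizon_h=48.0)
        tc2 = mk.rk4_solve(p, regimen(md=1000), horizon_h=48.0)
        np.testing.assert_allclose(
            tc2.central_conc_mg_L, 2.0 * tc1.central_conc_mg_L, rtol=1e-9, atol=1e-12
        )

    @settings(max_examples=20, deadline=None)
    @given(
        md_a=st.floats(100, 2000), md_b=st.floats(100, 2000),
        shift_h=st.integers(0, 24),
    )
    def test_superposition_of_event_lists(self, md_a, md_b, shift_h):
        """Simulating two schedules separately and summing equals their union."""
        p = params2()
        ev_a = regimen(md=md_a, interval=12.0, n=2)
        ev_b = mk.build_regimen("drug", md_b, 8.0, 2,
                                mk.EPOCH + timedelta(hours=shift_h), 30.0)
        h = 72.0
        sep = (
            mk.rk4_solve(p, ev_a, h, start=mk.EPOCH).central_conc_mg_L
            + mk.rk4_solve(p, ev_b, h, start=mk.EPOCH).central_conc_mg_L
        )
        union = mk.rk4_solve(p, ev_a + ev_b, h, start=mk.EPOCH).central_conc_mg_L
        np.testing.assert_allclose(union, sep, rtol=1e-9, atol=1e-12)

    def test_mass_balance_without_elimination(self):
        """With (near-)zero clearance the compartments hold the infused dose."""
        p = mk.IndividualParameters(cl_L_h=1e-12, v1_L=38.0, q_L_h=60.0, v2_L=73.0)
        tc = mk.rk4_solve(p, regimen(md=750, interval=12.0, n=3, inf_min=45), 40.0)
        total = tc.compartment_amounts_mg.sum(axis=1)
        assert total[-1] == pytest.approx(2250.0, rel=1e-9)

    def test_fourth_order_convergence_on_smooth_decay(self):
        """Halving the step cuts the error of pure exponential decay ~16x."""
        p = params1(cl=20.0, v1=10.0)  # k = 2 per hour: truncation error visible
        a0 = [1000.0]
        errs = []
        for step in (6.0, 3.0):
            tc = mk.rk4_solve(p, [], horizon_h=3.0, initial_amounts=a0, step_min=step)
            exact = (a0[0] / p.v1_L) * np.exp(-2.0 * tc.times_h)
            errs.append(np.max(np.abs(tc.central_conc_mg_L - exact)))
        ratio = errs[0] / errs[1]
        assert 12.0 < ratio < 20.0

    def test_eigen_propagation_equals_explicit_stepping(self):
        """The segment-wise affine propagation is the literal RK4 step loop."""
        p = params2()
        plan = _make_plan(regimen(md=800, interval=8.0, n=3, inf_min=30), mk.EPOCH,
                          24.0, 1.0)
        from mipdkit.simulate import _system_matrix
        M, N = _rk4_maps(_system_matrix(p), 1.0 / 60.0)
        fast = _run_plan(p, plan)
        slow = _run_plan_loop(M, N, plan, np.zeros(2))
        np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-9)

    def test_event_outside_horizon_rejected(self):
        late = [mk.DoseEvent("d", 100.0, mk.EPOCH + timedelta(hours=30))]
        with pytest.raises(ValueError, match="outside"):
            mk.rk4_solve(params1(), late, horizon_h=24.0, start=mk.EPOCH)

    def test_negative_initial_amounts_rejected(self):
        with pytest.raises(ValueError):
            mk.rk4_solve(params1(), [], 1.0, initial_amounts=[-5.0])


class TestClosedForm:
    def test_zero_at_time_zero(self):
        c = mk.closed_form_one_compartment(params1(), regimen(), [0.0])
        assert c[0] == 0.0

    def test_bolus_limit_dose_over_volume(self):
        p = params1(cl=1.0, v1=100.0)
        ev = [mk.DoseEvent("d", 1000.0, mk.EPOCH, infusion_duration_min=1.0)]
        c = mk.closed_form_one_compartment(p, ev, [1.0 / 60.0])
        assert c[0] == pytest.approx(10.0, rel=1e-3)  # within 1-min decay tolerance

    def test_decays_to_zero(self):
        c = mk.closed_form_one_compartment(params1(), regimen(n=2), [2000.0])
        assert c[0] == pytest.approx(0.0, abs=1e-12)

    def test_rejects_two_compartment_params(self):
        with pytest.raises(ValueError, match="rk4_solve"):
            mk.closed_form_one_compartment(params2(), regimen(), [1.0])


class TestExposure:
    def test_constant_concentration_rectangle_auc(self):
        p = params1(cl=1e-12, v1=1.0)  # no elimination: constant level
        tc = mk.rk4_solve(p, [], horizon_h=24.0, initial_amounts=[5.0])
        s = mk.summarize_exposure(tc, (0.0, 24.0), mic_mg_L=1.0)
        assert s.auc_mg_h_L == pytest.approx(120.0, rel=1e-9)
        assert s.pct_time_above_mic == 100.0
        assert s.cmin_mg_L == pytest.approx(s.cmax_mg_L)

    def test_steady_state_daily_auc_equals_dose_over_cl(self, vanc_params):
        ss = mk.steady_state_metrics(vanc_params, 1000.0, 12.0)
        assert ss.auc_mg_h_L == pytest.approx(2000.0 / vanc_params.cl_L_h, rel=0.01)

    def test_empty_window_rejected(self, vanc_params):
        tc = mk.rk4_solve(vanc_params, regimen(n=1), horizon_h=12.0)
        with pytest.raises(ValueError):
            mk.summarize_exposure(tc, (5.0, 5.0))
        with pytest.raises(ValueError):
            mk.summarize_exposure(tc, (0.0, 48.0))


class TestSteadyStateTiming:
    def test_hand_evaluated_one_compartment(self):
        p = params1(cl=4.58, v1=107.1)
        assert mk.terminal_half_life(p) == pytest.approx(16.21, abs=0.01)
        assert mk.time_to_steady_state(p) == pytest.approx(113.5, abs=0.1)

    def test_unit_rate_constant(self):
        p = params1(cl=3.3, v1=3.3)  # k = 1/h
        assert mk.time_to_steady_state(p) == pytest.approx(7.0 * math.log(2.0))

    def test_two_compartment_slower_than_central_elimination(self):
        p = params2()
        one = params1(cl=p.cl_L_h, v1=p.v1_L)
        assert mk.time_to_steady_state(p) >= mk.time_to_steady_state(one)

    def test_two_compartment_matches_terminal_log_slope(self):
        """Independent oracle: fit the terminal slope of a simulated decay."""
        p = params2()
        tc = mk.rk4_solve(p, [], horizon_h=48.0, initial_amounts=[1000.0, 0.0])
        t = tc.times_h
        c = tc.central_conc_mg_L
        tail = t > 24.0  # beyond distribution phase
        slope = np.polyfit(t[tail], np.log(c[tail]), 1)[0]
        assert mk.terminal_half_life(p) == pytest.approx(math.log(2.0) / -slope, rel=1e-3)


class TestTimeCourse:
    def test_csv_round_trip_shape(self, tmp_path, vanc_params):
        tc = mk.rk4_solve(vanc_params, regimen(n=1), horizon_h=2.0)
        path = tmp_path / "tc.csv"
        tc.to_csv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "time,concentration_mg_L"
        assert len(lines) == 1 + len(tc.central_conc_mg_L)

    def test_concentration_interpolation_consistent(self, vanc_params):
        tc = mk.rk4_solve(vanc_params, regimen(n=1), horizon_h=6.0)
        assert tc.concentration_at(3.0) == pytest.approx(tc.central_conc_mg_L[180])
        assert tc.concentration_at(mk.EPOCH + timedelta(hours=3)) == pytest.approx(
            tc.central_conc_mg_L[180]
        )
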