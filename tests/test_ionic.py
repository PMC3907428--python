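"""Single-cell membrane model: currents, gate updates, calcium, rest state."""

from dataclasses import replace

import numpy as np
import pytest

import cardiowave as cw
from cardiowave import kernels
from cardiowave.errors import (InvalidInputError, InvalidStateError,
                               NoRestStateError)
from cardiowave.ionic import DT_GATE_MAX, MembraneState
from cardiowave.rates import evaluate_rate


def mk_state(rest, **kw):
    return replace(rest, **kw)


class TestComputeCurrents:
    def test_closed_slow_gates_kill_i_s(self, rest, params):
        for kw in ({"d": 0.0}, {"f": 0.0}):
            st = mk_state(rest, vm=-20.0, cai=3e-7, **kw)
            assert cw.compute_currents(st, params).i_s == 0.0

    def test_closed_m_and_no_background_kill_i_na(self, rest, params):
        p = params.replace(g_nac=0.0)
        st = mk_state(rest, m=0.0)
        assert cw.compute_currents(st, p).i_na == 0.0

    def test_i_k1_continuous_through_its_singularity(self, rest, params):
        # (Vm+23)/(1-exp(-0.04(Vm+23))) has limit 25 at Vm = -23
        at = cw.compute_currents(mk_state(rest, vm=-23.0), params).i_k1
        for eps in (1e-6, -1e-6):
            near = cw.compute_currents(mk_state(rest, vm=-23.0 + eps),
                                       params).i_k1
            assert abs(near - at) < 1e-6

    def test_total_is_exact_sum(self, rest, params):
        c = cw.compute_currents(mk_state(rest, vm=-40.0, d=0.4, f=0.6), params)
        assert c.i_total == c.i_na + c.i_s + c.i_k1 + c.i_x1

    def test_nonpositive_cai_rejected(self, rest, params):
        bad = MembraneState(vm=rest.vm, m=0.1, h=0.1, j=0.1, d=0.1, f=0.1,
                            x1=0.1, cai=-1e-9)
        with pytest.raises(InvalidStateError):
            cw.compute_currents(bad, params)

    def test_j_gate_toggle_scales_i_na(self, rest, params):
        st = mk_state(rest, vm=-30.0, m=0.5, h=0.5, j=0.5)
        p_off = params.replace(use_j_gate=False, g_nac=0.0)
        p_on = params.replace(use_j_gate=True, g_nac=0.0)
        i_off = cw.compute_currents(st, p_off).i_na
        i_on = cw.compute_currents(st, p_on).i_na
        assert i_on == pytest.approx(0.5 * i_off, rel=1e-12)


class TestGateUpdates:
    def test_euler_formula_from_closed_gate(self):
        # g' = g + dt*(a*(1-g) - b*g); from g=0 with a=2, dt=0.1 -> 0.2
        assert kernels.gate_euler(0.0, 2.0, 7.3, 0.1) == pytest.approx(0.2)

    def test_steady_state_is_fixed_point(self, rest, params):
        out = cw.update_gates_euler(rest, params, dt=0.01)
        for g in ("m", "h", "d", "f", "x1"):
            assert getattr(out, g) == pytest.approx(getattr(rest, g),
                                                    abs=1e-15)
        assert out.vm == rest.vm and out.cai == rest.cai

    def test_clamp_bounds_output(self, rest, params):
        hot = mk_state(rest, vm=60.0, m=0.99)
        out = cw.update_gates_euler(hot, params, dt=0.009)
        for g in ("m", "h", "j", "d", "f", "x1"):
            assert 0.0 <= getattr(out, g) <= 1.0

    def test_one_step_maps_unit_interval_into_itself_below_dt_gate_max(
            self, params):
        # Sufficient condition: dt*(alpha+beta) <= 1 over the sanity range.
        for v in np.linspace(-120.0, 80.0, 401):
            for gate in ("m", "h", "j", "d", "f", "x1"):
                a = evaluate_rate(v, params.rate_table[f"{gate}.alpha"])
                b = evaluate_rate(v, params.rate_table[f"{gate}.beta"])
                assert DT_GATE_MAX * (a + b) <= 1.0

    def test_nonpositive_dt_rejected(self, rest, params):
        with pytest.raises(InvalidInputError):
            cw.update_gates_euler(rest, params, dt=0.0)


class TestCaiUpdate:
    def test_fixed_point(self, rest):
        st = mk_state(rest, cai=1e-7)
        assert cw.update_cai(st, i_s=0.0, dt=0.5) == pytest.approx(1e-7,
                                                                   rel=1e-14)

    def test_relaxation_arithmetic(self, rest):
        st = mk_state(rest, cai=2e-7)
        out = cw.update_cai(st, i_s=0.0, dt=1.0)
        assert out == pytest.approx(2e-7 + 0.07 * (1e-7 - 2e-7), rel=1e-12)

    def test_floor_clamp(self, rest):
        st = mk_state(rest, cai=1e-9)
        out = cw.update_cai(st, i_s=1e6, dt=1.0, cai_floor=1e-10)
        assert out == 1e-10


class TestSingleCellStep:
    def test_rest_is_fixed_point(self, rest, params):
        out = cw.single_cell_step(rest, params, i_stim=0.0, dt=0.01)
        assert np.max(np.abs(out.as_array() - rest.as_array())) < 1e-9

    def test_strong_stimulus_depolarizes_monotonically(self, rest, params):
        st = rest
        vms = [st.vm]
        for _ in range(50):   # 0.5 ms of a strong depolarizing pulse
            st = cw.single_cell_step(st, params, i_stim=80.0, dt=0.01)
            vms.append(st.vm)
        assert all(b > a for a, b in zip(vms, vms[1:]))

    def test_zero_dt_rejected(self, rest, params):
        with pytest.raises(InvalidInputError):
            cw.single_cell_step(rest, params, 0.0, dt=0.0)

    def test_state_change_first_order_in_dt(self, rest, params):
        st = mk_state(rest, vm=-60.0)
        d1 = cw.single_cell_step(st, params, 0.0, 1e-4).as_array() - st.as_array()
        d2 = cw.single_cell_step(st, params, 0.0, 2e-4).as_array() - st.as_array()
        np.testing.assert_allclose(d2, 2.0 * d1, rtol=1e-2, atol=1e-16)


class TestRestState:
    def test_rest_potential_in_physiological_band(self, rest):
        assert -90.0 < rest.vm < -75.0

    def test_gates_balance_at_rest(self, rest, params):
        for gate in ("m", "h", "j", "d", "f", "x1"):
            a = evaluate_rate(rest.vm, params.rate_table[f"{gate}.alpha"])
            b = evaluate_rate(rest.vm, params.rate_table[f"{gate}.beta"])
            g = getattr(rest, gate)
            assert abs(a * (1.0 - g) - b * g) < 1e-12

    def test_reduced_model_matches_independent_bisection(self, params):
        # With every inward conductance off, V* solves I_K1 + I_x1 = 0.
        # Independent oracle: direct numpy transcription of the closed forms,
        # bisected without any package code.
        p = params.replace(g_na=0.0, g_s=0.0, g_nac=0.0)

        def ix1_k1(v):
            ax1 = 0.0005 * np.exp(0.083 * (v + 50)) / (np.exp(0.057 * (v + 50)) + 1)
            bx1 = 0.0013 * np.exp(-0.06 * (v + 20)) / (np.exp(-0.04 * (v + 20)) + 1)
            x1 = ax1 / (ax1 + bx1)
            ik1 = 0.35 * (4 * (np.exp(0.04 * (v + 85)) - 1)
                          / (np.exp(0.08 * (v + 53)) + np.exp(0.04 * (v + 53)))
                          + 0.2 * (v + 23) / (1 - np.exp(-0.04 * (v + 23))))
            ix1 = x1 * 0.8 * (np.exp(0.04 * (v + 77)) - 1) / np.exp(0.04 * (v + 35))
            return ik1 + ix1

        lo, hi = -100.0, -60.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if ix1_k1(lo) * ix1_k1(mid) <= 0:
                hi = mid
            else:
                lo = mid
        oracle_v = 0.5 * (lo + hi)
        rest = cw.find_rest_state(p)
        assert rest.vm == pytest.approx(oracle_v, abs=1e-6)

    def test_missing_sign_change_raises(self, params):
        with pytest.raises(NoRestStateError):
            cw.find_rest_state(params, bracket=(-72.0, -60.0))


class TestActionPotential:
    def test_excitability_and_recovery(self, params):
        times, vm, _ = cw.simulate_cell(params, dt=0.01, duration=600.0,
                                        stim_amplitude=60.0, stim_start=0.0,
                                        stim_duration=2.0)
        rest_vm = vm[0]
        assert vm.max() > 0.0
        # the slow outward-gate tail brings Vm back within 1 mV of rest
        back = np.nonzero(np.abs(vm - rest_vm) < 1.0)[0]
        back = back[times[back] > 50.0]
        assert back.size and times[back[0]] < 600.0

    def test_determinism_bitwise(self, params):
        a = cw.simulate_cell(params, 0.01, 20.0, 60.0, 0.0, 2.0)[1]
        b = cw.simulate_cell(params, 0.01, 20.0, 60.0, 0.0, 2.0)[1]
        assert np.array_equal(a, b)

    def test_gate_stability_margin_along_trajectory(self, params):
        # dt*(alpha+beta) < 1 for every gate at every visited Vm: the clamp
        # never engages during a default action potential.
        _, vm, _ = cw.simulate_cell(params, 0.01, 500.0, 60.0, 0.0, 2.0)
        for v in np.unique(np.round(vm, 1)):
            for gate in ("m", "h", "d", "f", "x1"):
                a = evaluate_rate(float(v), params.rate_table[f"{gate}.alpha"])
                b = evaluate_rate(float(v), params.rate_table[f"{gate}.beta"])
                assert 0.01 * (a + b) < 1.0
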