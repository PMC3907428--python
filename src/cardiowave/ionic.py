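"""Single-cell electrophysiology: currents, gate kinetics, calcium dynamics
and the rest-state solve for the Beeler-Reuter model with Drouhard-Roberge
sodium kinetics.

All scalar arithmetic is delegated to the jitted kernels in
:mod:`cardiowave.kernels`, so a single cell stepped here is bit-identical to
a zero-diffusion tissue node stepped by any backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import kernels
from .errors import (InvalidInputError, InvalidStateError, NoRestStateError,
                     NumericalInstabilityError)
from .params import IonicParams
from .rates import evaluate_rate, gate_steady_state

#: Vm sanity bounds, mV; an excursion outside signals numerical instability
VM_MIN = -120.0
VM_MAX = 80.0

#: Largest dt (ms) for which one explicit-Euler gate update maps [0, 1] into
#: [0, 1] before clamping for every Vm in the sanity range.  The worst case
#: is the sodium deactivation rate at -120 mV (alpha+beta ~ 1320/ms); at
#: voltages a simulation actually visits the binding rates are an order of
#: magnitude smaller.
DT_GATE_MAX = 7e-4

#: Practical ionic time-step cap (ms) used by config validation; along
#: physiological trajectories (Vm in about [-90, +60] mV) the gate updates
#: remain monotone-stable here, and the [0, 1] clamp guards the rest.
DT_IONIC_CAP = 0.02

_GATES = ("m", "h", "j", "d", "f", "x1")


@dataclass(frozen=True)
class MembraneState:
    """One cell's transmembrane potential, gates and calcium concentration."""

    vm: float      # mV
    m: float
    h: float
    j: float
    d: float
    f: float
    x1: float
    cai: float     # mol/L

    def validate(self) -> None:
        for name in _GATES:
            g = getattr(self, name)
            if not 0.0 <= g <= 1.0:
                raise InvalidStateError(f"gate {name}={g} outside [0, 1]")
        if not self.cai > 0.0:
            raise InvalidStateError(f"Cai={self.cai} must be > 0")
        if not VM_MIN <= self.vm <= VM_MAX:
            raise InvalidStateError(
                f"Vm={self.vm} outside sanity bounds [{VM_MIN}, {VM_MAX}] mV")

    def as_array(self) -> np.ndarray:
        return np.array([self.vm, self.m, self.h, self.j, self.d, self.f,
                         self.x1, self.cai])


@dataclass(frozen=True)
class Currents:
    """Ionic current densities, uA/cm^2."""

    i_na: float
    i_s: float
    i_k1: float
    i_x1: float

    @property
    def i_total(self) -> float:
        return self.i_na + self.i_s + self.i_k1 + self.i_x1


def compute_currents(state: MembraneState, params: IonicParams) -> Currents:
    """All four ionic currents at the given state."""
    if not state.cai > 0.0:
        raise InvalidStateError(f"Cai={state.cai} must be > 0")
    i_na, i_s, i_k1, i_x1 = kernels.currents_eval(
        state.vm, state.m, state.h, state.j, state.d, state.f, state.x1,
        state.cai, params.g_na, params.e_na, params.g_nac, params.g_s,
        params.use_j_gate, params.singular_halfwidth)
    return Currents(float(i_na), float(i_s), float(i_k1), float(i_x1))


def update_gates_euler(state: MembraneState, params: IonicParams,
                       dt: float) -> MembraneState:
    """One Euler step of the active gates at the pre-step Vm.

    Gates are clamped to [0, 1] after the update; Vm and Cai are unchanged.
    With ``use_j_gate`` disabled the j gate is inert and keeps its value.
    """
    if not dt > 0.0:
        raise InvalidInputError("dt must be > 0")
    m, h, j, d, f, x1 = kernels.gates_step(
        state.vm, state.m, state.h, state.j, state.d, state.f, state.x1,
        params.packed_rates(), dt, params.singular_halfwidth,
        params.use_j_gate)
    return replace(state, m=float(m), h=float(h), j=float(j), d=float(d),
                   f=float(f), x1=float(x1))


def update_cai(state: MembraneState, i_s: float, dt: float,
               cai_floor: float = 1e-10) -> float:
    """Beeler-Reuter intracellular calcium update, floored at ``cai_floor``."""
    if not dt > 0.0:
        raise InvalidInputError("dt must be > 0")
    if not state.cai > 0.0:
        raise InvalidStateError("Cai must be > 0")
    return float(kernels.cai_step(state.cai, i_s, dt, cai_floor))


def single_cell_step(state: MembraneState, params: IonicParams,
                     i_stim: float, dt: float) -> MembraneState:
    """One full Euler step in the canonical order gates -> currents -> Cai -> Vm."""
    if not dt > 0.0:
        raise InvalidInputError("dt must be > 0")
    out = kernels.cell_step_scalar(
        state.vm, state.m, state.h, state.j, state.d, state.f, state.x1,
        state.cai, i_stim, params.packed_rates(), params.packed_scalars(), dt)
    vm = float(out[0])
    if not (VM_MIN <= vm <= VM_MAX):
        raise NumericalInstabilityError(
            f"Vm={vm} mV left sanity bounds after one step")
    return MembraneState(vm, *(float(x) for x in out[1:]))


def simulate_cell(params: IonicParams, dt: float, duration: float,
                  stim_amplitude: float = 0.0, stim_start: float = 0.0,
                  stim_duration: float = 0.0):
    """Integrate a single cell from rest; returns (times, vm_trace, final state).

    The stimulus is a rectangular current injection (uA/cm^2, depolarizing
    positive) active for t in [stim_start, stim_start + stim_duration).
    """
    state = find_rest_state(params)
    rates = params.packed_rates()
    pvec = params.packed_scalars()
    n_steps = int(math.floor(duration / dt))
    times = np.arange(n_steps + 1) * dt
    vm = np.empty(n_steps + 1)
    vm[0] = state.vm
    t_end = stim_start + stim_duration
    cur = (state.vm, state.m, state.h, state.j, state.d, state.f, state.x1,
           state.cai)
    for i in range(n_steps):
        t = i * dt
        ist = stim_amplitude if stim_start <= t < t_end else 0.0
        cur = kernels.cell_step_scalar(*cur, ist, rates, pvec, dt)
        if not (VM_MIN <= cur[0] <= VM_MAX):
            raise NumericalInstabilityError(
                f"Vm={cur[0]} mV left sanity bounds at t={t + dt} ms")
        vm[i + 1] = cur[0]
    return times, vm, MembraneState(*(float(x) for x in cur))


def _steady_cai(v: float, d_inf: float, f_inf: float,
                params: IonicParams) -> float:
    """Cai fixed point of the calcium ODE at fixed Vm and steady d, f."""
    cai = params.cai_init
    for _ in range(200):
        e_s = -82.3 - 13.0287 * math.log(cai)
        i_s = params.g_s * d_inf * f_inf * (v - e_s)
        new = 1e-7 - (1e-7 / 0.07) * i_s
        if new < params.cai_floor:
            new = params.cai_floor
        if abs(new - cai) < 1e-26:
            return new
        cai = new
    return cai


def _steady_state_at(v: float, params: IonicParams) -> MembraneState:
    gates = {}
    for name in _GATES:
        a = evaluate_rate(v, params.effective_spec(f"{name}.alpha"),
                          params.singular_halfwidth)
        b = evaluate_rate(v, params.effective_spec(f"{name}.beta"),
                          params.singular_halfwidth)
        gates[name], _ = gate_steady_state(a, b)
    cai = _steady_cai(v, gates["d"], gates["f"], params)
    return MembraneState(vm=v, cai=cai, **gates)


def _total_steady_current(v: float, params: IonicParams) -> float:
    return compute_currents(_steady_state_at(v, params), params).i_total


def find_rest_state(params: IonicParams,
                    bracket: tuple[float, float] = (-100.0, -60.0),
                    tol: float = 1e-9) -> MembraneState:
    """Quiescent membrane state: the zero of the steady-state total current.

    Each gate is set to its steady-state value g_inf(V*), Cai to its
    I_s-consistent fixed point, and V* is found by bisection on ``bracket``
    until |I_total| < ``tol`` uA/cm^2.
    """
    lo, hi = bracket
    f_lo = _total_steady_current(lo, params)
    f_hi = _total_steady_current(hi, params)
    if f_lo == 0.0:
        return _steady_state_at(lo, params)
    if f_hi == 0.0:
        return _steady_state_at(hi, params)
    if f_lo * f_hi > 0.0:
        raise NoRestStateError(
            f"steady-state I_total has no sign change on [{lo}, {hi}] mV "
            f"(I({lo})={f_lo:.3g}, I({hi})={f_hi:.3g}); check constants")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _total_steady_current(mid, params)
        if abs(f_mid) < tol or mid in (lo, hi):
            break
        if f_lo * f_mid < 0.0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return _steady_state_at(mid, params)
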