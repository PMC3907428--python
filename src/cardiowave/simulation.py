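"""The tissue time loop: stimulus protocols, reaction-diffusion Euler
stepping over structure-of-arrays state grids, protocol presets, backend
equivalence checking and tile autotuning.

Per-variable contiguous (SoA) storage is an invariant of
:class:`TissueState`: every state variable is its own (ny, nx) float64 grid,
never an interleaved per-node record.
"""

from __future__ import annotations

import copy
import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np

from .backends import make_stepper, parse_backend
from .diffusion import (FiberField, Grid2D, cfl_max_dt_fibers, node_weights,
                        pad_noflux)
from .errors import ConfigError, InvalidInputError, NumericalInstabilityError
from .ionic import (DT_IONIC_CAP, VM_MAX, VM_MIN, MembraneState,
                    find_rest_state)
from .params import IonicParams
from . import kernels

log = logging.getLogger("cardiowave")

#: fraction of the CFL bound that config validation allows dt to use
CFL_SAFETY = 0.9

_STATE_VARS = ("vm", "m", "h", "j", "d", "f", "x1", "cai")


@dataclass
class TissueState:
    """Structure-of-arrays tissue state: one contiguous grid per variable."""

    vm: np.ndarray
    m: np.ndarray
    h: np.ndarray
    j: np.ndarray
    d: np.ndarray
    f: np.ndarray
    x1: np.ndarray
    cai: np.ndarray
    t: float = 0.0
    step_idx: int = 0

    @classmethod
    def uniform(cls, grid: Grid2D, ms: MembraneState) -> "TissueState":
        arrays = {name: np.full(grid.shape, getattr(ms, name))
                  for name in _STATE_VARS}
        return cls(**arrays)

    def copy(self) -> "TissueState":
        return TissueState(
            **{name: getattr(self, name).copy() for name in _STATE_VARS},
            t=self.t, step_idx=self.step_idx)

    def node(self, ix: int, iy: int) -> MembraneState:
        return MembraneState(
            *(float(getattr(self, name)[iy, ix]) for name in _STATE_VARS))

    @property
    def shape(self) -> tuple[int, int]:
        return self.vm.shape


@dataclass
class StimEvent:
    """A timed rectangular current-injection event.

    ``region`` is (x0, x1, y0, y1) in node indices, half-open.  With
    ``trigger='time'`` the window is [t_start, t_end).  With
    ``trigger='auto'`` the event arms itself: it fires the first time the
    monitor node's Vm falls through ``threshold`` during repolarization,
    latching that time as the start of a window of the same duration
    (t_end - t_start); subsequent crossings are ignored.
    """

    t_start: float
    t_end: float
    region: tuple[int, int, int, int]
    amplitude: float
    trigger: str = "time"
    monitor: tuple[int, int] | None = None
    threshold: float = -50.0

    def __post_init__(self):
        self._latched_start: float | None = None
        self._prev_monitor: float | None = None

    def validate(self, grid: Grid2D) -> None:
        if not self.t_end > self.t_start:
            raise ConfigError("stimulus: t_end must exceed t_start")
        x0, x1, y0, y1 = self.region
        if not (0 <= x0 < x1 <= grid.nx and 0 <= y0 < y1 <= grid.ny):
            raise ConfigError(
                f"stimulus region {self.region} empty or outside grid "
                f"{grid.nx}x{grid.ny}")
        if self.trigger not in ("time", "auto"):
            raise ConfigError(f"unknown trigger {self.trigger!r}")
        if self.trigger == "auto":
            if self.monitor is None:
                raise ConfigError("auto-trigger stimulus needs a monitor node")
            mx, my = self.monitor
            if not (0 <= mx < grid.nx and 0 <= my < grid.ny):
                raise ConfigError("monitor node outside grid")

    def reset_runtime(self) -> None:
        self._latched_start = None
        self._prev_monitor = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def update_trigger(self, state: TissueState, t: float) -> bool:
        """Advance the auto-trigger latch; returns True if it latched now."""
        if self.trigger != "auto":
            return False
        mx, my = self.monitor
        cur = float(state.vm[my, mx])
        latched_now = False
        if (self._latched_start is None and self._prev_monitor is not None
                and self._prev_monitor > self.threshold >= cur):
            self._latched_start = t
            latched_now = True
        self._prev_monitor = cur
        return latched_now

    def window(self) -> tuple[float, float] | None:
        if self.trigger == "time":
            return (self.t_start, self.t_end)
        if self._latched_start is None:
            return None
        return (self._latched_start, self._latched_start + self.duration)


@dataclass
class SimConfig:
    """Everything a run needs; invariants enforced by :meth:`validate`."""

    grid: Grid2D
    fibers: FiberField = field(default_factory=FiberField)
    ionic: IonicParams = field(default_factory=IonicParams.default)
    dt: float = 0.01                 # ms
    duration: float = 100.0          # ms
    stimuli: list = field(default_factory=list)
    backend: str = "gather"
    tile_x: int = 16
    tile_y: int = 16
    workers: int = 1
    probe: tuple[int, int] | None = None   # (ix, iy); default domain center
    snapshot_every: float = 1.0      # ms of simulated time
    seed: int = 0                    # reserved; shipped dynamics deterministic

    def __post_init__(self):
        if self.probe is None:
            self.probe = (self.grid.nx // 2, self.grid.ny // 2)

    def validate(self) -> None:
        self.grid.validate()
        self.fibers.validate(self.grid)
        self.ionic.validate()
        if not self.duration > 0.0:
            raise ConfigError("duration must be > 0")
        if not self.dt > 0.0:
            raise ConfigError("dt must be > 0")
        dt_cfl = CFL_SAFETY * cfl_max_dt_fibers(self.fibers, self.grid)
        if self.dt > dt_cfl:
            raise ConfigError(
                f"dt={self.dt} ms violates the diffusion stability bound: "
                f"dt must be <= {dt_cfl:.6g} ms "
                f"({CFL_SAFETY} x CFL limit) for this grid and tensor")
        if self.dt > DT_IONIC_CAP:
            raise ConfigError(
                f"dt={self.dt} ms exceeds the ionic stiffness cap "
                f"{DT_IONIC_CAP} ms")
        if self.tile_x < 1 or self.tile_y < 1:
            raise ConfigError("tile sizes must be >= 1")
        if self.workers < 1:
            raise ConfigError("workers must be >= 1")
        px, py = self.probe
        if not (0 <= px < self.grid.nx and 0 <= py < self.grid.ny):
            raise ConfigError(f"probe {self.probe} outside grid")
        if not self.snapshot_every > 0.0:
            raise ConfigError("snapshot_every must be > 0")
        parse_backend(self.backend)
        for ev in self.stimuli:
            ev.validate(self.grid)

    @property
    def n_steps(self) -> int:
        return int(math.floor(self.duration / self.dt + 1e-9))

    def copy(self) -> "SimConfig":
        return copy.deepcopy(self)


@dataclass
class SimResult:
    """Probe trace, snapshots, final state and performance counters."""

    times: np.ndarray          # (n_steps+1,) ms
    probe_vm: np.ndarray       # (n_steps+1,) mV at the probe node
    snapshot_times: list
    snapshots: list            # Vm grids at the snapshot cadence
    final_state: TissueState
    steps: int
    node_updates: int
    elapsed_s: float           # stepping time only (I/O and copies excluded)
    stim_log: list             # (event index, resolved t_start) per firing
    config: SimConfig

    @property
    def nodes_per_second(self) -> float:
        return self.node_updates / self.elapsed_s if self.elapsed_s > 0 else math.inf


def init_tissue(config: SimConfig) -> TissueState:
    """Quiescent tissue: every node at the single-cell rest state."""
    rest = find_rest_state(config.ionic)
    return TissueState.uniform(config.grid, rest)


def apply_stimulus(state: TissueState, stimuli, t: float) -> np.ndarray:
    """Per-node injected current (uA/cm^2) at time t; overlapping events sum.

    Also advances the auto-trigger latches of the events, which fire at most
    once each.
    """
    out = np.zeros(state.shape)
    _fill_stimulus(out, state, stimuli, t, None)
    return out


def _fill_stimulus(out, state, stimuli, t, stim_log) -> None:
    out[:] = 0.0
    for idx, ev in enumerate(stimuli):
        if ev.update_trigger(state, t) and stim_log is not None:
            stim_log.append((idx, t))
        win = ev.window()
        if win is not None and win[0] <= t < win[1]:
            x0, x1, y0, y1 = ev.region
            out[y0:y1, x0:x1] += ev.amplitude


def _check_stable(ts: TissueState, step_no: int, last_snapshot) -> None:
    vm = ts.vm
    bad = ~((vm >= VM_MIN) & (vm <= VM_MAX))   # also catches NaN
    if bad.any():
        iy, ix = np.argwhere(bad)[0]
        raise NumericalInstabilityError(
            f"Vm={vm[iy, ix]!r} mV outside [{VM_MIN}, {VM_MAX}] at node "
            f"(x={ix}, y={iy}) on step {step_no}",
            step=step_no, node=(int(ix), int(iy)), last_snapshot=last_snapshot)


def _build_stepper(config: SimConfig):
    wgt = node_weights(config.fibers, config.grid)
    rates = config.ionic.packed_rates()
    pvec = config.ionic.packed_scalars()
    return make_stepper(config.backend, config.grid, wgt, rates, pvec,
                        config.dt, tile_x=config.tile_x, tile_y=config.tile_y,
                        workers=config.workers)


def step(state: TissueState, config: SimConfig) -> TissueState:
    """One Euler step of the whole tissue, in place; returns the state.

    Convenience wrapper for tests and interactive use; :func:`run` amortizes
    the setup over the whole loop.
    """
    config.validate()
    stepper = _build_stepper(config)
    try:
        istim = apply_stimulus(state, config.stimuli, state.t)
        stepper.step(state, istim)
        state.t += config.dt
        state.step_idx += 1
        _check_stable(state, state.step_idx, None)
    finally:
        stepper.close()
    return state


def recompute_node(state: TissueState, config: SimConfig, ix: int,
                   iy: int, i_stim: float = 0.0) -> MembraneState:
    """Recompute a single node's post-step value from the pre-step state.

    Within one time step node outputs depend only on pre-step values, so
    this isolated recomputation must reproduce the full step's result at
    (ix, iy) exactly.
    """
    wgt = node_weights(config.fibers, config.grid)
    rates = config.ionic.packed_rates()
    pvec = config.ionic.packed_scalars()
    vmp = pad_noflux(state.vm)
    scratch = {name: getattr(state, name).copy()
               for name in ("m", "h", "j", "d", "f", "x1", "cai")}
    vm_out = state.vm.copy()
    istim = np.full(state.shape, i_stim)
    kernels.update_block(vmp, wgt, istim, rates, pvec, config.dt,
                         iy, iy + 1, ix, ix + 1, vm_out,
                         scratch["m"], scratch["h"], scratch["j"],
                         scratch["d"], scratch["f"], scratch["x1"],
                         scratch["cai"])
    return MembraneState(
        float(vm_out[iy, ix]), float(scratch["m"][iy, ix]),
        float(scratch["h"][iy, ix]), float(scratch["j"][iy, ix]),
        float(scratch["d"][iy, ix]), float(scratch["f"][iy, ix]),
        float(scratch["x1"][iy, ix]), float(scratch["cai"][iy, ix]))


def run(config: SimConfig, initial: TissueState | None = None,
        record_snapshots: bool = True) -> SimResult:
    """Execute floor(duration/dt) Euler steps with the selected backend.

    Deterministic for a given config and backend family.  On numerical
    instability the raised error carries the last recorded snapshot.
    """
    config.validate()
    ts = initial.copy() if initial is not None else init_tissue(config)
    stimuli = copy.deepcopy(config.stimuli)
    for ev in stimuli:
        ev.reset_runtime()
    stepper = _build_stepper(config)

    n_steps = config.n_steps
    ny, nx = config.grid.shape
    px, py = config.probe
    times = np.arange(n_steps + 1) * config.dt
    probe_vm = np.empty(n_steps + 1)
    probe_vm[0] = ts.vm[py, px]
    snapshot_times: list[float] = []
    snapshots: list[np.ndarray] = []
    stim_log: list = []
    if record_snapshots:
        snapshot_times.append(ts.t)
        snapshots.append(ts.vm.copy())
    next_snap = 1
    istim = np.zeros((ny, nx))
    elapsed = 0.0
    try:
        for i in range(n_steps):
            t = times[i]
            _fill_stimulus(istim, ts, stimuli, t, stim_log)
            t0 = time.perf_counter()
            stepper.step(ts, istim)
            elapsed += time.perf_counter() - t0
            ts.t = float(times[i + 1])
            ts.step_idx += 1
            _check_stable(ts, ts.step_idx,
                          snapshots[-1] if snapshots else None)
            probe_vm[i + 1] = ts.vm[py, px]
            if record_snapshots and ts.t + 1e-9 >= next_snap * config.snapshot_every:
                snapshot_times.append(ts.t)
                snapshots.append(ts.vm.copy())
                next_snap = int(math.floor(ts.t / config.snapshot_every + 1e-9)) + 1
    finally:
        stepper.close()

    return SimResult(
        times=times, probe_vm=probe_vm, snapshot_times=snapshot_times,
        snapshots=snapshots, final_state=ts, steps=n_steps,
        node_updates=n_steps * nx * ny, elapsed_s=elapsed,
        stim_log=stim_log, config=config)


# ---------------------------------------------------------------------------
# Protocol presets
# ---------------------------------------------------------------------------

#: slow-inward kinetics speedup used by the reentry presets (the standard
#: device for bringing the spiral wavelength inside a tractable domain);
#: the breakup preset pushes it further to promote wavebreak
ROTOR_CA_SPEEDUP = 6.0
BREAKUP_CA_SPEEDUP = 8.0

_PROTOCOL_DEFAULT_GRIDS = {
    "plane_wave": 64,
    "single_rotor": 192,
    "breakup": 256,
}

#: default suprathreshold stimulus strength, uA/cm^2; strong enough to
#: capture partially recovered tissue, weak enough that a premature beat's
#: overshoot stays inside the Vm sanity bounds
STIM_AMPLITUDE = 40.0


def make_protocol(name: str, grid: Grid2D | None = None, *,
                  duration: float | None = None,
                  dt: float = 0.01,
                  ca_speedup: float | None = None,
                  s2_threshold: float = -50.0,
                  stim_amplitude: float = STIM_AMPLITUDE,
                  theta: float | None = None,
                  d_par: float | None = None,
                  d_perp: float | None = None,
                  backend: str = "gather",
                  snapshot_every: float = 1.0,
                  use_j_gate: bool | None = None) -> SimConfig:
    """Preset configurations for the standard study protocols.

    ``plane_wave``   S1 strip (5 columns at x=0, 2 ms) on isotropic tissue;
    ``single_rotor`` S1 plus an S2 over the lower-left quadrant that fires
                     automatically when the domain-center node repolarizes
                     through ``s2_threshold`` (cross-field S1-S2),
                     anisotropic fibers;
    ``breakup``      isotropic tissue, larger default grid, same S1-S2.

    All parameters can be overridden; the returned config passes its own
    invariants.
    """
    if name not in _PROTOCOL_DEFAULT_GRIDS:
        raise ConfigError(f"unknown protocol {name!r}; one of "
                          f"{tuple(_PROTOCOL_DEFAULT_GRIDS)}")
    if grid is None:
        n = _PROTOCOL_DEFAULT_GRIDS[name]
        grid = Grid2D(nx=n, ny=n)

    ionic_kw = {}
    if name == "plane_wave":
        fibers = FiberField(theta=0.0 if theta is None else theta,
                            d_par=0.001 if d_par is None else d_par,
                            d_perp=(d_par if d_perp is None and d_par is not None
                                    else 0.001 if d_perp is None else d_perp))
        duration = 60.0 if duration is None else duration
    elif name == "single_rotor":
        fibers = FiberField(theta=math.pi / 6 if theta is None else theta,
                            d_par=0.001 if d_par is None else d_par,
                            d_perp=0.0002 if d_perp is None else d_perp)
        ionic_kw["ca_speedup"] = (ROTOR_CA_SPEEDUP if ca_speedup is None
                                  else ca_speedup)
        duration = 560.0 if duration is None else duration
    else:  # breakup
        fibers = FiberField(theta=0.0 if theta is None else theta,
                            d_par=0.001 if d_par is None else d_par,
                            d_perp=0.001 if d_perp is None else d_perp)
        ionic_kw["ca_speedup"] = (BREAKUP_CA_SPEEDUP if ca_speedup is None
                                  else ca_speedup)
        duration = 600.0 if duration is None else duration
    if ca_speedup is not None:
        ionic_kw["ca_speedup"] = ca_speedup
    if use_j_gate is not None:
        ionic_kw["use_j_gate"] = use_j_gate
    ionic = IonicParams.default(**ionic_kw)

    stimuli = [StimEvent(t_start=0.0, t_end=2.0,
                         region=(0, min(5, grid.nx), 0, grid.ny),
                         amplitude=stim_amplitude)]
    if name in ("single_rotor", "breakup"):
        center = (grid.nx // 2, grid.ny // 2)
        stimuli.append(StimEvent(
            t_start=0.0, t_end=2.0,
            region=(0, grid.nx // 2, 0, grid.ny // 2),
            amplitude=stim_amplitude, trigger="auto", monitor=center,
            threshold=s2_threshold))

    return SimConfig(grid=grid, fibers=fibers, ionic=ionic, dt=dt,
                     duration=duration, stimuli=stimuli, backend=backend,
                     snapshot_every=snapshot_every)


# ---------------------------------------------------------------------------
# Backend equivalence and tile autotuning
# ---------------------------------------------------------------------------

#: sup-norm trajectory tolerances (mV)
TOL_READONLY = 1e-10
TOL_SCATTER = 1e-9


@dataclass
class EquivalenceReport:
    backends: list
    pairwise: dict          # (label_i, label_j) -> max |dVm| over nodes+steps
    tolerances: dict        # same keys -> allowed bound
    passed: bool

    def worst(self) -> float:
        return max(self.pairwise.values()) if self.pairwise else 0.0


def run_equivalence(config: SimConfig, backends,
                    n_steps: int | None = None) -> EquivalenceReport:
    """Run every backend on the identical configuration in lockstep and
    report pairwise sup-norm trajectory differences.

    The stimulus grid (including auto-trigger latching) is evaluated once
    per step from the first backend's state and shared, so all backends see
    the same input currents.
    """
    labels = [str(b) for b in backends]
    if len(labels) < 2:
        raise InvalidInputError("need at least two backends to compare")
    config.validate()
    if n_steps is None:
        n_steps = config.n_steps

    wgt = node_weights(config.fibers, config.grid)
    rates = config.ionic.packed_rates()
    pvec = config.ionic.packed_scalars()
    rest = init_tissue(config)
    states = [rest.copy() for _ in labels]
    steppers = [make_stepper(lbl, config.grid, wgt, rates, pvec, config.dt,
                             tile_x=config.tile_x, tile_y=config.tile_y,
                             workers=config.workers) for lbl in labels]
    stimuli = copy.deepcopy(config.stimuli)
    for ev in stimuli:
        ev.reset_runtime()

    pairs = [(labels[a], labels[b])
             for a in range(len(labels)) for b in range(a + 1, len(labels))]
    maxdiff = {p: 0.0 for p in pairs}
    istim = np.zeros(config.grid.shape)
    try:
        for i in range(n_steps):
            t = i * config.dt
            _fill_stimulus(istim, states[0], stimuli, t, None)
            for st, sp in zip(states, steppers):
                sp.step(st, istim)
            for a in range(len(labels)):
                for b in range(a + 1, len(labels)):
                    d = float(np.max(np.abs(states[a].vm - states[b].vm)))
                    key = (labels[a], labels[b])
                    if d > maxdiff[key]:
                        maxdiff[key] = d
    finally:
        for sp in steppers:
            sp.close()

    def tol_for(pair):
        return (TOL_SCATTER if any(parse_backend(x)[0] == "scatter"
                                   for x in pair) else TOL_READONLY)

    tols = {p: tol_for(p) for p in pairs}
    passed = all(maxdiff[p] <= tols[p] for p in pairs)
    return EquivalenceReport(backends=labels, pairwise=maxdiff,
                             tolerances=tols, passed=passed)


def autotune_tiles(config: SimConfig, candidates,
                   check_steps: int = 20, time_steps: int = 100):
    """Pick the fastest tile shape among ``candidates``.

    Correctness of every candidate is asserted with :func:`run_equivalence`
    against the gather backend first; each candidate is then timed on a
    fixed-step workload after one warm-up run.  Returns
    ``(best_tile, table)`` where table rows are dicts with tile shape and
    timing.
    """
    candidates = [(int(tx), int(ty)) for tx, ty in candidates]
    if not candidates:
        raise InvalidInputError("no tile candidates given")
    backends = ["gather"] + [f"tiled:{tx}x{ty}" for tx, ty in candidates]
    report = run_equivalence(config, backends, n_steps=check_steps)
    if not report.passed:
        raise NumericalInstabilityError(
            f"tile candidates disagree with gather: {report.pairwise}")

    table = []
    for tx, ty in candidates:
        cfg = config.copy()
        cfg.backend = "tiled"
        cfg.tile_x, cfg.tile_y = tx, ty
        cfg.duration = time_steps * cfg.dt
        run(cfg, record_snapshots=False)          # warm-up
        res = run(cfg, record_snapshots=False)
        table.append({"tile_x": tx, "tile_y": ty,
                      "elapsed_s": res.elapsed_s,
                      "nodes_per_s": res.nodes_per_second})
    best = min(table, key=lambda row: row["elapsed_s"])
    for row in table:
        log.info("autotune: tile %dx%d  %.4fs  %.0f nodes/s", row["tile_x"],
                 row["tile_y"], row["elapsed_s"], row["nodes_per_s"])
    log.info("autotune: best tile %dx%d", best["tile_x"], best["tile_y"])
    return (best["tile_x"], best["tile_y"]), table


def vulnerable_window_scan(grid: Grid2D | None = None,
                           thresholds=(-50.0, -60.0, -40.0),
                           window_ms: float = 300.0,
                           stop_on_success: bool = True,
                           **overrides):
    """Scan S2 auto-trigger thresholds for sustained reentry.

    For each threshold the single-rotor protocol is run and judged with
    :func:`cardiowave.metrics.sustained_reentry` over ``window_ms`` after
    the S2 firing.  Returns a list of records (threshold, s2 time,
    sustained flag, result).
    """
    from .metrics import sustained_reentry

    records = []
    for thr in thresholds:
        cfg = make_protocol("single_rotor", grid, s2_threshold=thr,
                            **overrides)
        res = run(cfg)
        s2 = next((t for idx, t in res.stim_log if idx == 1), None)
        sustained = False
        if s2 is not None:
            sustained = sustained_reentry(res, s2, window_ms=window_ms)
        records.append({"threshold": thr, "s2_time": s2,
                        "sustained": sustained, "result": res})
        if sustained and stop_on_success:
            break
    return records
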