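"""Quantitative readouts: excitation counts, activation maps, conduction
velocity, action-potential duration, sustained-reentry judgement, and the
nodes-per-second benchmark harness."""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .diffusion import Grid2D
from .errors import (InvalidInputError, NoActionPotentialError,
                     NotActivatedError)

#: default excitation threshold (mV) for activity counting
EXCITED_THRESHOLD = -30.0
#: default upstroke threshold (mV) for activation maps
UPSTROKE_THRESHOLD = -50.0

#: sentinel for never-activated nodes in an ActivationMap
NEVER = math.nan


@dataclass
class ActivationMap:
    """Per-node first upward-crossing time of a threshold (ms); NaN = never."""

    times: np.ndarray
    threshold: float

    @property
    def shape(self):
        return self.times.shape


@dataclass
class PerfRecord:
    """One benchmark measurement."""

    nx: int
    ny: int
    backend: str
    tile_x: int
    tile_y: int
    workers: int
    steps: int
    node_updates: int
    elapsed_s: float

    @property
    def nodes_per_second(self) -> float:
        return self.node_updates / self.elapsed_s if self.elapsed_s > 0 else math.inf


def count_excited(vm: np.ndarray, threshold: float = EXCITED_THRESHOLD) -> int:
    """Number of nodes with Vm strictly above the threshold."""
    return int(np.count_nonzero(vm > threshold))


def activation_map(result, threshold: float = UPSTROKE_THRESHOLD) -> ActivationMap:
    """First upward threshold crossing per node, from the run's snapshots.

    Crossing times are linearly interpolated between consecutive snapshots;
    a node already above threshold at the first snapshot activates at that
    snapshot's time; never-crossed nodes get the NaN sentinel.
    """
    if not result.snapshots:
        raise InvalidInputError("result has no snapshots")
    times = np.full(result.snapshots[0].shape, NEVER)
    prev_t = result.snapshot_times[0]
    prev = result.snapshots[0]
    already = prev > threshold
    times[already] = prev_t
    done = already.copy()
    for t, snap in zip(result.snapshot_times[1:], result.snapshots[1:]):
        crossing = (~done) & (prev <= threshold) & (snap > threshold)
        if crossing.any():
            frac = (threshold - prev[crossing]) / (snap[crossing] - prev[crossing])
            times[crossing] = prev_t + frac * (t - prev_t)
            done |= crossing
        prev_t, prev = t, snap
    return ActivationMap(times=times, threshold=threshold)


def conduction_velocity(amap: ActivationMap, grid: Grid2D, row: int,
                        x_range: tuple[int, int]) -> float:
    """Wavefront speed (cm/ms) along one row between two columns."""
    x0, x1 = x_range
    t0 = amap.times[row, x0]
    t1 = amap.times[row, x1]
    if math.isnan(t0) or math.isnan(t1):
        raise NotActivatedError(
            f"node in range not activated (row {row}, cols {x0}..{x1})")
    if not t1 > t0:
        raise InvalidInputError("activation times not increasing over range")
    return (x1 - x0) * grid.dx / (t1 - t0)


def apd(times: np.ndarray, vm: np.ndarray, level: float = 0.9) -> float:
    """Action-potential duration at the given repolarization level.

    The AP amplitude is peak minus baseline (the trace's first sample); the
    duration is the time spent above the level-fraction recovery potential
    ``V_L = baseline + (1 - level) * amplitude``, i.e. APD90 for level=0.9,
    with linear interpolation at both crossings.  The trace must contain a
    single upstroke and recovery.
    """
    times = np.asarray(times, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if times.shape != vm.shape or times.size < 3:
        raise InvalidInputError("times and vm must be equal-length (>= 3)")
    if not 0.0 < level <= 1.0:
        raise InvalidInputError("level must be in (0, 1]")
    baseline = vm[0]
    peak_idx = int(np.argmax(vm))
    amplitude = vm[peak_idx] - baseline
    if amplitude < 20.0:    # mV; smaller excursions are not action potentials
        raise NoActionPotentialError(
            f"no upstroke found (amplitude {amplitude:.2f} mV)")
    v_l = baseline + (1.0 - level) * amplitude

    up = None
    for i in range(peak_idx):
        if vm[i] <= v_l < vm[i + 1]:
            up = times[i] + (v_l - vm[i]) / (vm[i + 1] - vm[i]) * (times[i + 1] - times[i])
            break
    down = None
    for i in range(peak_idx, vm.size - 1):
        if vm[i] >= v_l > vm[i + 1]:
            down = times[i] + (vm[i] - v_l) / (vm[i] - vm[i + 1]) * (times[i + 1] - times[i])
            break
    if up is None or down is None:
        raise NoActionPotentialError("trace lacks a full upstroke/recovery")
    return float(down - up)


def probe_activations(times: np.ndarray, vm: np.ndarray,
                      threshold: float = EXCITED_THRESHOLD,
                      t_min: float = -math.inf,
                      t_max: float = math.inf) -> int:
    """Count upward threshold crossings of a probe trace within [t_min, t_max]."""
    sel = (times >= t_min) & (times <= t_max)
    v = vm[sel]
    if v.size < 2:
        return 0
    return int(np.count_nonzero((v[:-1] <= threshold) & (v[1:] > threshold)))


def sustained_reentry(result, t_after: float, window_ms: float = 300.0,
                      excited_threshold: float = EXCITED_THRESHOLD,
                      min_probe_activations: int = 3) -> bool:
    """Judge whether activity after ``t_after`` constitutes sustained reentry.

    Requires (a) at least one excited node at every snapshot in
    (t_after, t_after + window_ms], and (b) at least
    ``min_probe_activations`` distinct activations of the probe node in that
    window -- which rules out a single decaying wave.
    """
    t_end = t_after + window_ms
    if result.times[-1] + 1e-9 < t_end:
        raise InvalidInputError(
            f"run too short to judge: needs t >= {t_end} ms, "
            f"have {result.times[-1]} ms")
    in_window = [count_excited(s, excited_threshold) > 0
                 for t, s in zip(result.snapshot_times, result.snapshots)
                 if t_after < t <= t_end]
    if not in_window or not all(in_window):
        return False
    n_act = probe_activations(result.times, result.probe_vm,
                              excited_threshold, t_after, t_end)
    return n_act >= min_probe_activations


def benchmark(configs, steps: int | None = None) -> list[PerfRecord]:
    """Time a fixed-step workload for each config (one record per config).

    Snapshot and probe output is excluded from the timed region; counters
    are exact integer bookkeeping.  Timing values are reported, never
    asserted -- they are hardware facts.
    """
    from .simulation import run

    records = []
    for cfg in configs:
        cfg = cfg.copy()
        if steps is not None:
            cfg.duration = steps * cfg.dt
        res = run(cfg, record_snapshots=False)
        records.append(PerfRecord(
            nx=cfg.grid.nx, ny=cfg.grid.ny, backend=cfg.backend,
            tile_x=cfg.tile_x, tile_y=cfg.tile_y, workers=cfg.workers,
            steps=res.steps, node_updates=res.node_updates,
            elapsed_s=res.elapsed_s))
    return records


def write_benchmark_csv(records, path) -> None:
    """Machine-readable benchmark table."""
    cols = ["nx", "ny", "backend", "tile_x", "tile_y", "workers", "steps",
            "node_updates", "elapsed_s", "nodes_per_s"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for r in records:
            w.writerow([r.nx, r.ny, r.backend, r.tile_x, r.tile_y, r.workers,
                        r.steps, r.node_updates, repr(r.elapsed_s),
                        repr(r.nodes_per_second)])
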