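"""Configuration parsing, snapshot/trace persistence, run manifests and
programmatic fixture generation.

The config file is flat, diff-friendly ``key = value`` text; unknown keys
are errors (no silent typos) and missing keys take the documented defaults.
Snapshots use a small documented little-endian binary format; probe traces
are CSV at full float precision.
"""

from __future__ import annotations

import datetime
import json
import logging
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _code_version
from .diffusion import FiberField, Grid2D, cfl_max_dt_fibers
from .errors import ConfigError, InvalidInputError, SnapshotFormatError
from .ionic import find_rest_state
from .params import IonicParams
from .simulation import SimConfig, StimEvent, TissueState, run

log = logging.getLogger("cardiowave")

# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "nx": int, "ny": int, "dx": float, "dy": float,
    "theta": "angle", "d_par": float, "d_perp": float,
    "dt": float, "duration": float, "backend": str,
    "tile_x": int, "tile_y": int, "workers": int,
    "probe_x": int, "probe_y": int, "snapshot_every": float, "seed": int,
    "ca_speedup": float, "use_j_gate": bool, "params_file": str,
}
_STIM_KEYS = {
    "t_start": float, "t_end": float, "x0": int, "x1": int, "y0": int,
    "y1": int, "amplitude": float, "trigger": str, "monitor_x": int,
    "monitor_y": int, "threshold": float,
}


def _parse_angle(value: str) -> float:
    """Angles are radians by default; a 'deg' suffix converts from degrees."""
    v = value.strip()
    if v.endswith("deg"):
        return math.radians(float(v[:-3].strip()))
    if v.endswith("rad"):
        v = v[:-3].strip()
    return float(v)


def _convert(key, typ, value, where):
    try:
        if typ is bool:
            if value.lower() not in ("true", "false"):
                raise ValueError
            return value.lower() == "true"
        if typ == "angle":
            return _parse_angle(value)
        return typ(value)
    except ValueError:
        raise ConfigError(f"{where}: bad value {value!r} for key {key!r}") from None


def load_config(path) -> SimConfig:
    """Parse a flat key=value config file into a validated SimConfig."""
    path = Path(path)
    return parse_config(path.read_text(), source=str(path))


def parse_config(text: str, source: str = "<string>") -> SimConfig:
    top: dict = {}
    stims: dict[int, dict] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        where = f"{source}:{lineno}"
        if "=" not in line:
            raise ConfigError(f"{where}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("stim."):
            parts = key.split(".")
            if len(parts) != 3 or parts[2] not in _STIM_KEYS:
                raise ConfigError(f"{where}: unknown key {key!r}")
            try:
                idx = int(parts[1])
            except ValueError:
                raise ConfigError(f"{where}: bad stimulus index in {key!r}") from None
            stims.setdefault(idx, {})[parts[2]] = _convert(
                key, _STIM_KEYS[parts[2]], value, where)
        elif key in _TOP_KEYS:
            top[key] = _convert(key, _TOP_KEYS[key], value, where)
        else:
            raise ConfigError(f"{where}: unknown key {key!r}")

    grid = Grid2D(nx=top.get("nx", 64), ny=top.get("ny", 64),
                  dx=top.get("dx", 0.025), dy=top.get("dy", 0.025))
    d_par = top.get("d_par", 0.001)
    fibers = FiberField(theta=top.get("theta", 0.0), d_par=d_par,
                        d_perp=top.get("d_perp", d_par))
    ionic_kw = {}
    if "ca_speedup" in top:
        ionic_kw["ca_speedup"] = top["ca_speedup"]
    if "use_j_gate" in top:
        ionic_kw["use_j_gate"] = top["use_j_gate"]
    if "params_file" in top:
        ionic = IonicParams.from_file(top["params_file"], **ionic_kw)
    else:
        ionic = IonicParams.default(**ionic_kw)

    stimuli = []
    for idx in sorted(stims):
        s = stims[idx]
        required = {"t_start", "t_end", "x0", "x1", "y0", "y1", "amplitude"}
        missing = required - set(s)
        if missing:
            raise ConfigError(
                f"{source}: stim.{idx} missing keys {sorted(missing)}")
        monitor = None
        if "monitor_x" in s or "monitor_y" in s:
            monitor = (s.get("monitor_x", 0), s.get("monitor_y", 0))
        stimuli.append(StimEvent(
            t_start=s["t_start"], t_end=s["t_end"],
            region=(s["x0"], s["x1"], s["y0"], s["y1"]),
            amplitude=s["amplitude"], trigger=s.get("trigger", "time"),
            monitor=monitor, threshold=s.get("threshold", -50.0)))

    probe = None
    if "probe_x" in top or "probe_y" in top:
        probe = (top.get("probe_x", grid.nx // 2),
                 top.get("probe_y", grid.ny // 2))
    cfg = SimConfig(
        grid=grid, fibers=fibers, ionic=ionic,
        dt=top.get("dt", 0.01), duration=top.get("duration", 100.0),
        stimuli=stimuli, backend=top.get("backend", "gather"),
        tile_x=top.get("tile_x", 16), tile_y=top.get("tile_y", 16),
        workers=top.get("workers", 1), probe=probe,
        snapshot_every=top.get("snapshot_every", 1.0),
        seed=top.get("seed", 0))
    cfg.validate()
    return cfg


def dump_config(cfg: SimConfig) -> str:
    """Serialize a SimConfig to the flat text format (round-trips)."""
    if not isinstance(cfg.fibers.theta, float) and not np.isscalar(cfg.fibers.theta):
        raise InvalidInputError("per-node fiber fields cannot be dumped to "
                                "the flat config format")
    lines = [
        f"nx = {cfg.grid.nx}", f"ny = {cfg.grid.ny}",
        f"dx = {cfg.grid.dx!r}", f"dy = {cfg.grid.dy!r}",
        f"theta = {float(cfg.fibers.theta)!r}",
        f"d_par = {cfg.fibers.d_par!r}", f"d_perp = {cfg.fibers.d_perp!r}",
        f"dt = {cfg.dt!r}", f"duration = {cfg.duration!r}",
        f"backend = {cfg.backend}",
        f"tile_x = {cfg.tile_x}", f"tile_y = {cfg.tile_y}",
        f"workers = {cfg.workers}",
        f"probe_x = {cfg.probe[0]}", f"probe_y = {cfg.probe[1]}",
        f"snapshot_every = {cfg.snapshot_every!r}",
        f"seed = {cfg.seed}",
        f"ca_speedup = {cfg.ionic.ca_speedup!r}",
        f"use_j_gate = {'true' if cfg.ionic.use_j_gate else 'false'}",
    ]
    if cfg.ionic.source.startswith("builtin:"):
        pass  # default table; no params_file line needed
    else:
        lines.append(f"params_file = {cfg.ionic.source}")
    for i, ev in enumerate(cfg.stimuli):
        x0, x1, y0, y1 = ev.region
        lines += [
            f"stim.{i}.t_start = {ev.t_start!r}",
            f"stim.{i}.t_end = {ev.t_end!r}",
            f"stim.{i}.x0 = {x0}", f"stim.{i}.x1 = {x1}",
            f"stim.{i}.y0 = {y0}", f"stim.{i}.y1 = {y1}",
            f"stim.{i}.amplitude = {ev.amplitude!r}",
            f"stim.{i}.trigger = {ev.trigger}",
        ]
        if ev.monitor is not None:
            lines += [f"stim.{i}.monitor_x = {ev.monitor[0]}",
                      f"stim.{i}.monitor_y = {ev.monitor[1]}"]
        lines.append(f"stim.{i}.threshold = {ev.threshold!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Snapshot files
# ---------------------------------------------------------------------------

SNAPSHOT_MAGIC = b"CWSNAP1\0"
_HEADER = struct.Struct("<8sIIddd16s")   # magic, nx, ny, dx, dy, time, varname


def write_snapshot(path, grid_values: np.ndarray, grid: Grid2D,
                   time_ms: float, varname: str = "vm") -> None:
    """Write one state grid: 56-byte header + row-major little-endian f64."""
    arr = np.ascontiguousarray(grid_values, dtype="<f8")
    if arr.shape != grid.shape:
        raise InvalidInputError(f"grid values {arr.shape} != {grid.shape}")
    name = varname.encode()[:16].ljust(16, b"\0")
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(SNAPSHOT_MAGIC, grid.nx, grid.ny,
                              grid.dx, grid.dy, time_ms, name))
        fh.write(arr.tobytes())


def read_snapshot(path):
    """Read a snapshot; returns (values, meta dict). Bit-exact round trip."""
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < _HEADER.size:
            raise SnapshotFormatError("truncated header")
        magic, nx, ny, dx, dy, t, name = _HEADER.unpack(head)
        if magic != SNAPSHOT_MAGIC:
            raise SnapshotFormatError(f"bad magic {magic!r}")
        payload = fh.read()
    expected = nx * ny * 8
    if len(payload) != expected:
        raise SnapshotFormatError(
            f"payload {len(payload)} bytes, expected {expected}")
    arr = np.frombuffer(payload, dtype="<f8").reshape(ny, nx).copy()
    meta = {"nx": nx, "ny": ny, "dx": dx, "dy": dy, "time_ms": t,
            "varname": name.rstrip(b"\0").decode()}
    return arr, meta


# ---------------------------------------------------------------------------
# Probe traces
# ---------------------------------------------------------------------------

def write_probe_trace(path, times, vm) -> None:
    """Two-column CSV (time_ms, vm_mV) at 17 significant digits."""
    with open(path, "w") as fh:
        fh.write("time_ms,vm_mV\n")
        for t, v in zip(np.asarray(times), np.asarray(vm)):
            fh.write(f"{t:.17g},{v:.17g}\n")


def read_probe_trace(path):
    times, vm = [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "time_ms,vm_mV":
            raise InvalidInputError(f"unexpected trace header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            a, b = line.split(",")
            times.append(float(a))
            vm.append(float(b))
    return np.array(times), np.array(vm)


# ---------------------------------------------------------------------------
# Run manifest and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to reproduce a run exactly."""

    config_text: str
    constants_sha256: str
    code_version: str
    started: str
    finished: str = ""
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def run_and_save(cfg: SimConfig, outdir) -> tuple:
    """Run a simulation and persist trace, snapshots and manifest.

    Returns (SimResult, manifest_path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.validate()
    margin = cfg.dt / cfl_max_dt_fibers(cfg.fibers, cfg.grid)
    log.info("run: backend=%s tile=%dx%d workers=%d grid=%dx%d dt=%g ms "
             "(%.0f%% of CFL bound)", cfg.backend, cfg.tile_x, cfg.tile_y,
             cfg.workers, cfg.grid.nx, cfg.grid.ny, cfg.dt, 100 * margin)
    manifest = RunManifest(
        config_text=dump_config(cfg),
        constants_sha256=cfg.ionic.source_sha256,
        code_version=_code_version,
        started=datetime.datetime.now().isoformat(timespec="seconds"))
    result = run(cfg)
    outputs = []
    trace_path = outdir / "probe_trace.csv"
    write_probe_trace(trace_path, result.times, result.probe_vm)
    outputs.append(trace_path.name)
    for t, snap in zip(result.snapshot_times, result.snapshots):
        p = outdir / f"vm_{t:010.3f}ms.snap"
        write_snapshot(p, snap, cfg.grid, t)
        outputs.append(p.name)
    config_path = outdir / "config.txt"
    config_path.write_text(manifest.config_text)
    outputs.append(config_path.name)
    manifest.finished = datetime.datetime.now().isoformat(timespec="seconds")
    manifest.outputs = outputs
    manifest_path = outdir / "manifest.json"
    manifest.write(manifest_path)
    return result, manifest_path


# ---------------------------------------------------------------------------
# Fixture generation (deterministic test surfaces)
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("impulse", "plane", "random", "symmetric")


def make_fixture(kind: str, grid: Grid2D, seed: int = 0,
                 params: IonicParams | None = None) -> TissueState:
    """Deterministic tissue-state fixtures for tests and experiments.

    ``impulse``    rest tissue with one perturbed (0 mV) center node;
    ``plane``      rest tissue with an excited (0 mV) 5-column strip at x=0;
    ``random``     seeded uniform Vm in [-90, 20] mV with rest gates;
    ``symmetric``  random mirrored left-right.
    """
    if kind not in FIXTURE_KINDS:
        raise InvalidInputError(f"unknown fixture kind {kind!r}")
    params = params or IonicParams.default()
    rest = find_rest_state(params)
    ts = TissueState.uniform(grid, rest)
    rng = np.random.default_rng(seed)
    if kind == "impulse":
        ts.vm[grid.ny // 2, grid.nx // 2] = 0.0
    elif kind == "plane":
        ts.vm[:, :min(5, grid.nx)] = 0.0
    elif kind == "random":
        ts.vm[:] = rng.uniform(-90.0, 20.0, grid.shape)
    elif kind == "symmetric":
        half_w = (grid.nx + 1) // 2
        half = rng.uniform(-90.0, 20.0, (grid.ny, half_w))
        for jx in range(half_w):
            ts.vm[:, jx] = half[:, jx]
            ts.vm[:, grid.nx - 1 - jx] = half[:, jx]
    return ts
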