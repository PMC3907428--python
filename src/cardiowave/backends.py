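"""Interchangeable compute backends for the tissue time step.

Each backend embodies one of the kernel-optimization strategies studied for
this model, mapped to hardware-independent CPU form:

``reference``  staged scalar passes (gate update pass, then currents/Vm
               pass, then ghost refresh) -- the original nested-loop
               algorithm with one function per stage;
``gather``     single fused neighbor-update-free pass: each node reads its
               padded neighborhood and writes only itself;
``scatter``    direct port of the neighbor-writing formulation: a separate
               diffusion pass accumulates per-source writes, then the ionic
               update runs; kept as the cross-check oracle;
``tiled``      the gather kernel executed over cache-sized (tile_y, tile_x)
               blocks -- the block-size analogue;
``parallel``   the gather kernel over contiguous row strips executed by a
               thread pool -- the multi-core analogue.  Bit-identical for
               any worker count because every node is written exactly once
               from read-only inputs.

All backends share the scalar kernels of :mod:`cardiowave.kernels`; the
read-only family (reference/gather/tiled/parallel) is bit-identical, the
scatter backend differs only in diffusion accumulation order.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor

import numpy as np

from . import kernels
from .diffusion import _pad_into
from .errors import ConfigError

BACKEND_NAMES = ("reference", "gather", "scatter", "tiled", "parallel")


class _StepperBase:
    """Holds the packed model arrays and the ghost-padded Vm buffer."""

    def __init__(self, grid, wgt, rates, pvec, dt):
        self.grid = grid
        self.wgt = wgt
        self.rates = rates
        self.pvec = pvec
        self.dt = dt
        ny, nx = grid.shape
        self.vmp = np.empty((ny + 2, nx + 2))
        self.vm_out = np.empty((ny, nx))

    def close(self) -> None:
        pass

    def _swap(self, ts) -> None:
        ts.vm, self.vm_out = self.vm_out, ts.vm

    def step(self, ts, istim) -> None:
        raise NotImplementedError


class ReferenceStepper(_StepperBase):
    def step(self, ts, istim):
        ny, nx = self.grid.shape
        _pad_into(self.vmp, ts.vm)                      # bcs stage, serialized
        kernels.gates_block(ts.vm, self.rates, self.pvec, self.dt,
                            0, ny, 0, nx,
                            ts.m, ts.h, ts.j, ts.d, ts.f, ts.x1)
        kernels.currents_block(self.vmp, self.wgt, istim, self.rates,
                               self.pvec, self.dt, 0, ny, 0, nx,
                               self.vm_out, ts.m, ts.h, ts.j, ts.d, ts.f,
                               ts.x1, ts.cai)
        self._swap(ts)


class GatherStepper(_StepperBase):
    def step(self, ts, istim):
        ny, nx = self.grid.shape
        _pad_into(self.vmp, ts.vm)
        kernels.update_block(self.vmp, self.wgt, istim, self.rates,
                             self.pvec, self.dt, 0, ny, 0, nx,
                             self.vm_out, ts.m, ts.h, ts.j, ts.d, ts.f,
                             ts.x1, ts.cai)
        self._swap(ts)


class ScatterStepper(_StepperBase):
    def __init__(self, grid, wgt, rates, pvec, dt):
        super().__init__(grid, wgt, rates, pvec, dt)
        self.dvm = np.empty(grid.shape)

    def step(self, ts, istim):
        ny, nx = self.grid.shape
        _pad_into(self.vmp, ts.vm)
        kernels.scatter_diffusion(self.vmp, self.wgt, self.dvm)
        kernels.update_block_dv(ts.vm, self.dvm, istim, self.rates,
                                self.pvec, self.dt, 0, ny, 0, nx,
                                self.vm_out, ts.m, ts.h, ts.j, ts.d, ts.f,
                                ts.x1, ts.cai)
        self._swap(ts)


class TiledStepper(_StepperBase):
    def __init__(self, grid, wgt, rates, pvec, dt, tile_x, tile_y):
        super().__init__(grid, wgt, rates, pvec, dt)
        if tile_x < 1 or tile_y < 1:
            raise ConfigError("tile sizes must be >= 1")
        self.tile_x = int(tile_x)
        self.tile_y = int(tile_y)

    def step(self, ts, istim):
        ny, nx = self.grid.shape
        _pad_into(self.vmp, ts.vm)
        for r0 in range(0, ny, self.tile_y):
            r1 = min(r0 + self.tile_y, ny)
            for c0 in range(0, nx, self.tile_x):
                c1 = min(c0 + self.tile_x, nx)
                kernels.update_block(self.vmp, self.wgt, istim, self.rates,
                                     self.pvec, self.dt, r0, r1, c0, c1,
                                     self.vm_out, ts.m, ts.h, ts.j, ts.d,
                                     ts.f, ts.x1, ts.cai)
        self._swap(ts)


class ParallelStepper(_StepperBase):
    """Row-strip decomposition over a thread pool (kernels release the GIL)."""

    def __init__(self, grid, wgt, rates, pvec, dt, workers):
        super().__init__(grid, wgt, rates, pvec, dt)
        if workers < 1:
            raise ConfigError("worker count must be >= 1")
        self.workers = int(workers)
        ny = grid.ny
        bounds = np.linspace(0, ny, self.workers + 1).astype(int)
        self.strips = [(int(bounds[i]), int(bounds[i + 1]))
                       for i in range(self.workers)
                       if bounds[i] < bounds[i + 1]]
        self._pool = (ThreadPoolExecutor(max_workers=self.workers)
                      if len(self.strips) > 1 else None)

    def step(self, ts, istim):
        nx = self.grid.nx
        _pad_into(self.vmp, ts.vm)

        def work(strip):
            r0, r1 = strip
            kernels.update_block(self.vmp, self.wgt, istim, self.rates,
                                 self.pvec, self.dt, r0, r1, 0, nx,
                                 self.vm_out, ts.m, ts.h, ts.j, ts.d, ts.f,
                                 ts.x1, ts.cai)

        if self._pool is None:
            work(self.strips[0])
        else:
            list(self._pool.map(work, self.strips))
        self._swap(ts)

    def close(self):
        if self._pool is not None:
            self._pool.shutdown(wait=True)
            self._pool = None


def parse_backend(spec) -> tuple[str, dict]:
    """Parse a backend spec: a name, ``tiled:8x16``, or ``parallel:4``."""
    if isinstance(spec, tuple):
        return spec[0], dict(spec[1])
    name, _, arg = str(spec).partition(":")
    if name not in BACKEND_NAMES:
        raise ConfigError(f"unknown backend {name!r}; one of {BACKEND_NAMES}")
    opts: dict = {}
    if arg:
        if name == "tiled":
            tx, _, ty = arg.partition("x")
            opts = {"tile_x": int(tx), "tile_y": int(ty or tx)}
        elif name == "parallel":
            opts = {"workers": int(arg)}
        else:
            raise ConfigError(f"backend {name!r} takes no argument")
    return name, opts


def make_stepper(name, grid, wgt, rates, pvec, dt, *, tile_x=16, tile_y=16,
                 workers=1, **opts) -> _StepperBase:
    name, inline_opts = parse_backend(name)
    tile_x = inline_opts.get("tile_x", opts.get("tile_x", tile_x))
    tile_y = inline_opts.get("tile_y", opts.get("tile_y", tile_y))
    workers = inline_opts.get("workers", opts.get("workers", workers))
    if name == "reference":
        return ReferenceStepper(grid, wgt, rates, pvec, dt)
    if name == "gather":
        return GatherStepper(grid, wgt, rates, pvec, dt)
    if name == "scatter":
        return ScatterStepper(grid, wgt, rates, pvec, dt)
    if name == "tiled":
        return TiledStepper(grid, wgt, rates, pvec, dt, tile_x, tile_y)
    if name == "parallel":
        return ParallelStepper(grid, wgt, rates, pvec, dt, workers)
    raise ConfigError(f"unknown backend {name!r}")
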