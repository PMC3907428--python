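"""Anisotropic diffusion of transmembrane potential on a rectilinear grid.

Fiber-rotated 2x2 diffusion tensor, its 9-point finite-difference stencil
(centered second differences plus the 4-corner cross-derivative), no-flux
boundaries via a ghost-cell frame, and the explicit-Euler stability bound.

Coordinate convention: row index = y, column index = x, row-major storage,
0-based, node (0, 0) at the domain's lower-left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import kernels
from .errors import InvalidInputError


@dataclass(frozen=True)
class Grid2D:
    """Node counts and spacing (cm) of the rectilinear grid."""

    nx: int
    ny: int
    dx: float = 0.025
    dy: float = 0.025

    def validate(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise InvalidInputError("grid must be at least 3x3 nodes")
        if self.dx <= 0.0 or self.dy <= 0.0:
            raise InvalidInputError("grid spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) array shape for per-node grids."""
        return (self.ny, self.nx)


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric positive-semidefinite diffusion tensor, cm^2/ms."""

    dxx: float
    dyy: float
    dxy: float = 0.0

    def validate(self) -> None:
        if self.dxx < 0.0 or self.dyy < 0.0:
            raise InvalidInputError("diagonal diffusion entries must be >= 0")
        if self.dxx * self.dyy < self.dxy ** 2 - 1e-15 * max(self.dxx, self.dyy, 1.0) ** 2:
            raise InvalidInputError("diffusion tensor not positive semidefinite")


@dataclass(frozen=True)
class StencilWeights:
    """3x3 finite-difference weights (1/ms when applied to a mV grid).

    ``w[di, dj]`` multiplies the neighbor at row offset di-1 (y) and column
    offset dj-1 (x); w[1, 1] is the center.
    """

    w: np.ndarray

    def flat(self) -> np.ndarray:
        return np.ascontiguousarray(self.w.reshape(9))


@dataclass(frozen=True)
class FiberField:
    """Fiber angle (radians, uniform scalar or per-node grid) and the
    along/across-fiber diffusion coefficients (cm^2/ms)."""

    theta: float | np.ndarray = 0.0
    d_par: float = 0.001
    d_perp: float = 0.001

    def validate(self, grid: Grid2D | None = None) -> None:
        if self.d_perp > self.d_par:
            raise InvalidInputError("D_perp must not exceed D_par")
        if self.d_perp < 0.0:
            raise InvalidInputError("diffusion coefficients must be >= 0")
        if isinstance(self.theta, np.ndarray) and grid is not None:
            if self.theta.shape != grid.shape:
                raise InvalidInputError(
                    f"per-node theta shape {self.theta.shape} != {grid.shape}")

    @property
    def uniform(self) -> bool:
        return not isinstance(self.theta, np.ndarray)


def tensor_from_fibers(theta: float, d_par: float,
                       d_perp: float) -> DiffusionTensor:
    """Rotate the fiber-frame diagonal tensor diag(D_par, D_perp) by theta."""
    if d_perp > d_par:
        raise InvalidInputError("D_perp must not exceed D_par (anisotropy)")
    if d_perp < 0.0:
        raise InvalidInputError("diffusion coefficients must be >= 0")
    c = math.cos(theta)
    s = math.sin(theta)
    dxx = d_par * c * c + d_perp * s * s
    dyy = d_par * s * s + d_perp * c * c
    dxy = (d_par - d_perp) * s * c
    return DiffusionTensor(dxx=dxx, dyy=dyy, dxy=dxy)


def stencil_weights(tensor: DiffusionTensor, grid: Grid2D) -> StencilWeights:
    """9-point stencil for Dxx Vxx + 2 Dxy Vxy + Dyy Vyy.

    Axis weights Dxx/dx^2 (E, W) and Dyy/dy^2 (N, S); corner weights
    +-Dxy/(2 dx dy) with + on NE/SW and - on NW/SE; center balances the sum
    to zero exactly.
    """
    tensor.validate()
    wx = tensor.dxx / (grid.dx * grid.dx)
    wy = tensor.dyy / (grid.dy * grid.dy)
    wc = tensor.dxy / (2.0 * grid.dx * grid.dy)
    w = np.array([
        [+wc, wy, -wc],   # south row (y-1): SW, S, SE
        [wx, -2.0 * wx - 2.0 * wy, wx],
        [-wc, wy, +wc],   # north row (y+1): NW, N, NE
    ])
    return StencilWeights(w=w)


def pad_noflux(vm: np.ndarray) -> np.ndarray:
    """Ghost-cell frame implementing zero normal flux (even reflection).

    Each ghost takes the value of its adjacent interior node (reflection
    across the domain face); corner ghosts mirror diagonally.  The interior
    is copied untouched.
    """
    return np.pad(vm, 1, mode="edge")


def _pad_into(vmp: np.ndarray, vm: np.ndarray) -> None:
    """In-place ghost refresh of a preallocated (ny+2, nx+2) buffer."""
    vmp[1:-1, 1:-1] = vm
    vmp[0, 1:-1] = vm[0]
    vmp[-1, 1:-1] = vm[-1]
    vmp[:, 0] = vmp[:, 1]
    vmp[:, -1] = vmp[:, -2]


def node_weights(fibers: FiberField, grid: Grid2D) -> np.ndarray:
    """(ny, nx, 9) per-node stencil weights.

    For a uniform fiber angle all rows are identical; per-node angles get
    individually rotated tensors and weights.
    """
    fibers.validate(grid)
    if fibers.uniform:
        w9 = stencil_weights(
            tensor_from_fibers(float(fibers.theta), fibers.d_par,
                               fibers.d_perp), grid).flat()
        out = np.empty((grid.ny, grid.nx, 9))
        out[:, :] = w9
        return out
    out = np.empty((grid.ny, grid.nx, 9))
    for i in range(grid.ny):
        for jx in range(grid.nx):
            w9 = stencil_weights(
                tensor_from_fibers(float(fibers.theta[i, jx]), fibers.d_par,
                                   fibers.d_perp), grid).flat()
            out[i, jx] = w9
    return out


def _uniform_weight_grid(w: StencilWeights, grid: Grid2D) -> np.ndarray:
    out = np.empty((grid.ny, grid.nx, 9))
    out[:, :] = w.flat()
    return out


def apply_diffusion_gather(vm: np.ndarray, w: StencilWeights,
                           grid: Grid2D) -> np.ndarray:
    """dVm/dt grid (mV/ms); each node reads its padded 3x3 neighborhood."""
    if vm.shape != grid.shape:
        raise InvalidInputError(f"Vm shape {vm.shape} != grid {grid.shape}")
    vmp = pad_noflux(np.asarray(vm, dtype=np.float64))
    out = np.empty(grid.shape)
    kernels.gather_diffusion(vmp, _uniform_weight_grid(w, grid), out,
                             0, grid.ny, 0, grid.nx)
    return out


def apply_diffusion_scatter(vm: np.ndarray, w: StencilWeights,
                            grid: Grid2D) -> np.ndarray:
    """dVm/dt grid by accumulating per-source writes in row-major order.

    Mathematically equal to the gather result; serves as the cross-check
    oracle for the neighbor-update-free (gather) transformation.
    """
    if vm.shape != grid.shape:
        raise InvalidInputError(f"Vm shape {vm.shape} != grid {grid.shape}")
    vmp = pad_noflux(np.asarray(vm, dtype=np.float64))
    out = np.empty(grid.shape)
    kernels.scatter_diffusion(vmp, _uniform_weight_grid(w, grid), out)
    return out


def cfl_max_dt(tensor: DiffusionTensor, grid: Grid2D) -> float:
    """Conservative explicit-Euler stability bound for the 9-point scheme:

    dt_max = 1 / (2 (Dxx/dx^2 + Dyy/dy^2 + |Dxy|/(dx dy))).
    """
    tensor.validate()
    s = (tensor.dxx / grid.dx ** 2 + tensor.dyy / grid.dy ** 2
         + abs(tensor.dxy) / (grid.dx * grid.dy))
    if s == 0.0:
        return math.inf
    return 1.0 / (2.0 * s)


def cfl_max_dt_fibers(fibers: FiberField, grid: Grid2D) -> float:
    """Worst-case CFL bound over the fiber field (handles per-node theta)."""
    if fibers.uniform:
        return cfl_max_dt(
            tensor_from_fibers(float(fibers.theta), fibers.d_par,
                               fibers.d_perp), grid)
    thetas = np.unique(np.round(np.asarray(fibers.theta), 12))
    return min(
        cfl_max_dt(tensor_from_fibers(float(t), fibers.d_par, fibers.d_perp),
                   grid)
        for t in thetas)
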