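"""Anisotropic diffusion operator: tensor rotation, stencil, boundaries,
gather/scatter equivalence and stability bound."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardiowave as cw
from cardiowave.diffusion import (FiberField, cfl_max_dt_fibers, node_weights,
                                  pad_noflux)
from cardiowave.errors import InvalidInputError
from conftest import rng_grid


class TestTensorFromFibers:
    @pytest.mark.parametrize("theta,expect", [
        (0.0, (1.0, 0.2, 0.0)),
        (math.pi / 2, (0.2, 1.0, 0.0)),
        (math.pi / 4, (0.6, 0.6, 0.4)),
    ])
    def test_known_rotations(self, theta, expect):
        t = cw.tensor_from_fibers(theta, 1.0, 0.2)
        assert (t.dxx, t.dyy, t.dxy) == pytest.approx(expect, abs=1e-15)

    def test_inverted_anisotropy_rejected(self):
        with pytest.raises(InvalidInputError):
            cw.tensor_from_fibers(0.3, 0.2, 1.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(theta=st.floats(-math.pi, math.pi),
           d_perp=st.floats(0.0, 1.0), extra=st.floats(0.0, 1.0))
    def test_trace_preserved_and_psd(self, theta, d_perp, extra):
        d_par = d_perp + extra
        t = cw.tensor_from_fibers(theta, d_par, d_perp)
        assert t.dxx + t.dyy == pytest.approx(d_par + d_perp, rel=1e-12)
        assert t.dxx * t.dyy - t.dxy ** 2 >= -1e-15 * max(1.0, d_par) ** 2
        t.validate()


class TestStencilWeights:
    def test_isotropic_is_five_point_laplacian(self, small_grid):
        grid = cw.Grid2D(5, 5, dx=1.0, dy=1.0)
        w = cw.stencil_weights(cw.DiffusionTensor(1.0, 1.0, 0.0), grid).w
        assert w[1, 1] == -4.0
        assert w[0, 1] == w[2, 1] == w[1, 0] == w[1, 2] == 1.0
        assert w[0, 0] == w[0, 2] == w[2, 0] == w[2, 2] == 0.0

    def test_cross_derivative_corner_signs(self):
        grid = cw.Grid2D(5, 5, dx=1.0, dy=1.0)
        w = cw.stencil_weights(cw.DiffusionTensor(1.0, 1.0, 0.4), grid).w
        # + on NE (north=+y is the last row) and SW, - on NW and SE
        assert w[2, 2] == pytest.approx(0.2) and w[0, 0] == pytest.approx(0.2)
        assert w[2, 0] == pytest.approx(-0.2) and w[0, 2] == pytest.approx(-0.2)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(theta=st.floats(0.0, math.pi), d_perp=st.floats(1e-5, 1e-3),
           ratio=st.floats(1.0, 10.0))
    def test_weights_sum_to_zero(self, theta, d_perp, ratio):
        grid = cw.Grid2D(4, 4, dx=0.025, dy=0.02)
        t = cw.tensor_from_fibers(theta, d_perp * ratio, d_perp)
        w = cw.stencil_weights(t, grid).w
        assert abs(w.sum()) <= 1e-12 * np.abs(w).max()

    def test_180_degree_rotation_symmetry(self):
        grid = cw.Grid2D(4, 4, dx=0.03, dy=0.02)
        t = cw.tensor_from_fibers(0.7, 2e-3, 5e-4)
        w = cw.stencil_weights(t, grid).w
        np.testing.assert_array_equal(w, w[::-1, ::-1])


class TestPadNoflux:
    def test_constant_grid_stays_constant(self):
        p = pad_noflux(np.full((4, 5), 3.25))
        assert (p == 3.25).all()

    def test_ghosts_mirror_adjacent_interior(self):
        vm = np.arange(9.0).reshape(3, 3)
        p = pad_noflux(vm)
        # west ghost column of the padded array equals its first interior
        # column (even reflection across the domain face)
        np.testing.assert_array_equal(p[1:-1, 0], vm[:, 0])
        np.testing.assert_array_equal(p[1:-1, -1], vm[:, -1])
        np.testing.assert_array_equal(p[0, 1:-1], vm[0])
        np.testing.assert_array_equal(p[-1, 1:-1], vm[-1])
        assert p[0, 0] == vm[0, 0] and p[-1, -1] == vm[-1, -1]

    def test_interior_untouched_and_idempotent_core(self):
        vm = rng_grid((6, 7), seed=3)
        p = pad_noflux(vm)
        np.testing.assert_array_equal(p[1:-1, 1:-1], vm)
        pp = pad_noflux(p)
        np.testing.assert_array_equal(pp[1:-1, 1:-1], p)


class TestGatherScatter:
    def test_uniform_field_gives_zero_everywhere(self, iso_weights, small_grid):
        vm = np.full(small_grid.shape, -84.0)
        out = cw.apply_diffusion_gather(vm, iso_weights, small_grid)
        assert np.abs(out).max() == 0.0

    def test_unit_impulse_reproduces_stencil(self):
        grid = cw.Grid2D(7, 7, dx=1.0, dy=1.0)
        w = cw.stencil_weights(cw.DiffusionTensor(1.0, 1.0, 0.0), grid)
        vm = np.zeros(grid.shape)
        vm[3, 3] = 1.0
        out = cw.apply_diffusion_gather(vm, w, grid)
        expect = np.zeros(grid.shape)
        expect[3, 3] = -4.0
        for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            expect[3 + di, 3 + dj] = 1.0
        np.testing.assert_array_equal(out, expect)
        np.testing.assert_array_equal(
            cw.apply_diffusion_scatter(vm, w, grid), expect)

    @pytest.mark.parametrize("seed", range(12))
    def test_scatter_equals_gather_on_random_fields(self, seed):
        rng = np.random.default_rng(seed)
        grid = cw.Grid2D(int(rng.integers(3, 24)), int(rng.integers(3, 24)),
                         dx=0.025, dy=0.02)
        t = cw.tensor_from_fibers(rng.uniform(0, math.pi),
                                  1e-3, rng.uniform(1e-4, 1e-3))
        w = cw.stencil_weights(t, grid)
        vm = rng.uniform(-90, 20, grid.shape)
        g = cw.apply_diffusion_gather(vm, w, grid)
        s = cw.apply_diffusion_scatter(vm, w, grid)
        assert np.abs(g - s).max() < 1e-9

    def test_axis_aligned_conservation(self):
        grid = cw.Grid2D(32, 24)
        t = cw.tensor_from_fibers(0.0, 1e-3, 2e-4)
        w = cw.stencil_weights(t, grid)
        for seed in range(5):
            vm = rng_grid(grid.shape, seed)
            out = cw.apply_diffusion_gather(vm, w, grid)
            assert abs(out.sum()) < 1e-9 * np.abs(out).sum()

    def test_maximum_principle_axis_aligned(self):
        grid = cw.Grid2D(24, 24)
        t = cw.tensor_from_fibers(0.0, 1e-3, 1e-3)
        w = cw.stencil_weights(t, grid)
        dt = 0.95 * cw.cfl_max_dt(t, grid)
        vm = rng_grid(grid.shape, seed=11)
        lo, hi = vm.min(), vm.max()
        for _ in range(20):
            vm = vm + dt * cw.apply_diffusion_gather(vm, w, grid)
        assert vm.min() >= lo - 1e-12 and vm.max() <= hi + 1e-12

    def test_rotational_consistency_quarter_turn(self):
        # theta = pi/2 on the transposed grid equals the theta = 0 solution
        # transposed
        ga = cw.Grid2D(nx=10, ny=7)
        gb = cw.Grid2D(nx=7, ny=10)
        wa = cw.stencil_weights(cw.tensor_from_fibers(0.0, 1e-3, 2e-4), ga)
        wb = cw.stencil_weights(
            cw.tensor_from_fibers(math.pi / 2, 1e-3, 2e-4), gb)
        vm = rng_grid(ga.shape, seed=5)
        out_a = cw.apply_diffusion_gather(vm, wa, ga)
        out_b = cw.apply_diffusion_gather(vm.T, wb, gb)
        np.testing.assert_allclose(out_b, out_a.T, atol=1e-12)

    def test_left_right_symmetry_preserved(self):
        grid = cw.Grid2D(12, 9)
        w = cw.stencil_weights(cw.tensor_from_fibers(0.0, 1e-3, 1e-3), grid)
        vm = rng_grid((9, 6), seed=8)
        vm = np.hstack([vm, vm[:, ::-1]])
        out = cw.apply_diffusion_gather(vm, w, grid)
        np.testing.assert_allclose(out, out[:, ::-1], atol=1e-13)


class TestCflBound:
    def test_isotropic_unit_value(self):
        grid = cw.Grid2D(4, 4, dx=1.0, dy=1.0)
        assert cw.cfl_max_dt(cw.DiffusionTensor(1.0, 1.0, 0.0), grid) == 0.25

    def test_cross_term_tightens_bound(self):
        grid = cw.Grid2D(4, 4, dx=1.0, dy=1.0)
        assert cw.cfl_max_dt(cw.DiffusionTensor(1.0, 1.0, 0.5),
                             grid) == pytest.approx(0.2)

    def test_coarser_grid_relaxes_bound(self):
        t = cw.DiffusionTensor(1e-3, 1e-3, 0.0)
        d1 = cw.cfl_max_dt(t, cw.Grid2D(4, 4, dx=0.025, dy=0.025))
        d2 = cw.cfl_max_dt(t, cw.Grid2D(4, 4, dx=0.05, dy=0.05))
        assert d2 == pytest.approx(4.0 * d1)

    def test_zero_tensor_gives_infinity(self):
        grid = cw.Grid2D(4, 4)
        assert cw.cfl_max_dt(cw.DiffusionTensor(0.0, 0.0, 0.0), grid) == math.inf


class TestFiberField:
    def test_per_node_theta_matches_uniform(self):
        grid = cw.Grid2D(6, 5)
        uni = FiberField(theta=0.6, d_par=1e-3, d_perp=2e-4)
        per = FiberField(theta=np.full(grid.shape, 0.6), d_par=1e-3,
                         d_perp=2e-4)
        np.testing.assert_array_equal(node_weights(uni, grid),
                                      node_weights(per, grid))
        assert cfl_max_dt_fibers(uni, grid) == pytest.approx(
            cfl_max_dt_fibers(per, grid))

    def test_shape_mismatch_rejected(self):
        grid = cw.Grid2D(6, 5)
        bad = FiberField(theta=np.zeros((4, 4)), d_par=1e-3, d_perp=2e-4)
        with pytest.raises(InvalidInputError):
            bad.validate(grid)
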