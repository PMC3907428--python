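"""Numba scalar kernels shared by the single-cell operations and every tissue
backend.

All backends (reference, gather, scatter, tiled, parallel) call the same
inlined per-node helpers defined here, so any two backends that feed a node
the same inputs produce bit-identical outputs.  The only permitted numerical
divergence between backends is the accumulation order of the diffusion
stencil in the scatter formulation.

Parameter packing convention (see :class:`cardiowave.params.IonicParams`):

``R``  -- (12, 9) float64 rate table, rows ordered
          m.alpha, m.beta, h.alpha, h.beta, j.alpha, j.beta,
          d.alpha, d.beta, f.alpha, f.beta, x1.alpha, x1.beta;
          columns c1..c7, singular_v (nan if none), singular_limit.
``pv`` -- float64 vector [g_na, e_na, g_nac, g_s, c_m, use_j, cai_floor,
          singular_halfwidth].
"""

import math

from numba import njit

# Factored exponential offsets for the Beeler-Reuter I_K1 / I_x1 closed
# forms: every exp in those currents is exp(0.04*(V+c)) for some c, so a
# single e53 = exp(0.04*(V+53)) evaluation serves them all.
_E128 = math.exp(1.28)  # exp(0.04*(V+85))  = e53 * _E128
_E120 = math.exp(1.20)  # exp(-0.04*(V+23)) = _E120 / e53
_E096 = math.exp(0.96)  # exp(0.04*(V+77))  = e53 * _E096
_E072 = math.exp(0.72)  # exp(-0.04*(V+35)) = _E072 / e53

IK1_SINGULAR_V = -23.0
IK1_SINGULAR_LIMIT = 25.0  # lim_{V->-23} (V+23)/(1-exp(-0.04(V+23))) = 1/0.04


@njit(cache=True, inline="always")
def rate_eval(v, r, shw):
    """Canonical-form rate function, removable singularity handled.

    rate(V) = (c1*exp(c2*(V+c3)) + c4*(V+c5)) / (exp(c6*(V+c3)) + c7),
    returning the stored analytic limit within ``shw`` of the singular point.
    c1 == 0 / c6 == 0 short-circuit the corresponding exp so that pure
    polynomial or pure exponential specs cannot overflow through a dead term.
    """
    sv = r[7]
    if sv == sv and abs(v - sv) < shw:  # sv==sv filters the nan sentinel
        return r[8]
    if r[0] != 0.0:
        num = r[0] * math.exp(r[1] * (v + r[2])) + r[3] * (v + r[4])
    else:
        num = r[3] * (v + r[4])
    if r[5] != 0.0:
        den = math.exp(r[5] * (v + r[2])) + r[6]
    else:
        den = 1.0 + r[6]
    return num / den


@njit(cache=True, inline="always")
def clamp01(g):
    if g < 0.0:
        return 0.0
    if g > 1.0:
        return 1.0
    return g


@njit(cache=True, inline="always")
def gate_euler(g, a, b, dt):
    return clamp01(g + dt * (a * (1.0 - g) - b * g))


@njit(cache=True, inline="always")
def gates_step(v, m, h, j, d, f, x1, R, dt, shw, use_j):
    """One explicit-Euler update of the Hodgkin-Huxley gates at fixed Vm."""
    m = gate_euler(m, rate_eval(v, R[0], shw), rate_eval(v, R[1], shw), dt)
    h = gate_euler(h, rate_eval(v, R[2], shw), rate_eval(v, R[3], shw), dt)
    if use_j:
        j = gate_euler(j, rate_eval(v, R[4], shw), rate_eval(v, R[5], shw), dt)
    d = gate_euler(d, rate_eval(v, R[6], shw), rate_eval(v, R[7], shw), dt)
    f = gate_euler(f, rate_eval(v, R[8], shw), rate_eval(v, R[9], shw), dt)
    x1 = gate_euler(x1, rate_eval(v, R[10], shw), rate_eval(v, R[11], shw), dt)
    return m, h, j, d, f, x1


@njit(cache=True, inline="always")
def currents_eval(v, m, h, j, d, f, x1, cai, g_na, e_na, g_nac, g_s, use_j, shw):
    """All four ionic current densities (uA/cm^2) at one node."""
    gna_eff = g_na * m * m * m * h
    if use_j:
        gna_eff = gna_eff * j
    i_na = (gna_eff + g_nac) * (v - e_na)

    e_s = -82.3 - 13.0287 * math.log(cai)
    i_s = g_s * d * f * (v - e_s)

    e53 = math.exp(0.04 * (v + 53.0))
    ik1a = 4.0 * (e53 * _E128 - 1.0) / (e53 * e53 + e53)
    if abs(v - IK1_SINGULAR_V) < shw:
        ik1b = IK1_SINGULAR_LIMIT
    else:
        ik1b = (v + 23.0) / (1.0 - _E120 / e53)
    i_k1 = 0.35 * (ik1a + 0.2 * ik1b)

    i_x1 = x1 * 0.8 * (e53 * _E096 - 1.0) * (_E072 / e53)
    return i_na, i_s, i_k1, i_x1


@njit(cache=True, inline="always")
def cai_step(cai, i_s, dt, floor):
    cai = cai + dt * (-1e-7 * i_s + 0.07 * (1e-7 - cai))
    if cai < floor:
        cai = floor
    return cai


@njit(cache=True, inline="always")
def integrate_node(v, m, h, j, d, f, x1, cai, dv, ist,
                   g_na, e_na, g_nac, g_s, inv_cm, use_j, floor, shw, dt):
    """Currents -> Cai -> Vm update, given already-updated gates."""
    i_na, i_s, i_k1, i_x1 = currents_eval(
        v, m, h, j, d, f, x1, cai, g_na, e_na, g_nac, g_s, use_j, shw)
    cai2 = cai_step(cai, i_s, dt, floor)
    i_total = i_na + i_s + i_k1 + i_x1
    v2 = v + dt * (dv + (ist - i_total) * inv_cm)
    return v2, cai2


@njit(cache=True, inline="always")
def cell_update(v, m, h, j, d, f, x1, cai, dv, ist, R, pv, dt):
    """Full canonical-order node update: gates -> currents -> Cai -> Vm."""
    g_na = pv[0]
    e_na = pv[1]
    g_nac = pv[2]
    g_s = pv[3]
    inv_cm = 1.0 / pv[4]
    use_j = pv[5] > 0.5
    floor = pv[6]
    shw = pv[7]
    m, h, j, d, f, x1 = gates_step(v, m, h, j, d, f, x1, R, dt, shw, use_j)
    v2, cai2 = integrate_node(v, m, h, j, d, f, x1, cai, dv, ist,
                              g_na, e_na, g_nac, g_s, inv_cm, use_j, floor,
                              shw, dt)
    return v2, m, h, j, d, f, x1, cai2


@njit(cache=True)
def cell_step_scalar(v, m, h, j, d, f, x1, cai, ist, R, pv, dt):
    """Single-cell step: identical arithmetic to a zero-diffusion tissue node."""
    return cell_update(v, m, h, j, d, f, x1, cai, 0.0, ist, R, pv, dt)


# ---------------------------------------------------------------------------
# Block kernels over ghost-padded Vm grids.  All inner loops are branch-free
# with respect to the boundary: the ghost frame removes edge special cases
# (loop-unswitched form), so one kernel serves interior and edge nodes alike.
# ---------------------------------------------------------------------------

@njit(cache=True, nogil=True)
def update_block(vmp, wgt, istim, R, pv, dt, r0, r1, c0, c1,
                 vm_out, m, h, j, d, f, x1, cai):
    """Fused gather step on rows [r0, r1) and columns [c0, c1).

    Reads the padded pre-step Vm (``vmp``) and per-node stencil weights
    ``wgt`` (ny, nx, 9); writes vm_out and updates gate/Cai grids in place.
    Each node writes only its own entries, so blocks/strips may execute
    concurrently and in any order.
    """
    for i in range(r0, r1):
        for jx in range(c0, c1):
            w = wgt[i, jx]
            dv = (w[0] * vmp[i, jx] + w[1] * vmp[i, jx + 1] + w[2] * vmp[i, jx + 2]
                  + w[3] * vmp[i + 1, jx] + w[4] * vmp[i + 1, jx + 1]
                  + w[5] * vmp[i + 1, jx + 2]
                  + w[6] * vmp[i + 2, jx] + w[7] * vmp[i + 2, jx + 1]
                  + w[8] * vmp[i + 2, jx + 2])
            v2, m2, h2, j2, d2, f2, x2, ca2 = cell_update(
                vmp[i + 1, jx + 1], m[i, jx], h[i, jx], j[i, jx], d[i, jx],
                f[i, jx], x1[i, jx], cai[i, jx], dv, istim[i, jx], R, pv, dt)
            vm_out[i, jx] = v2
            m[i, jx] = m2
            h[i, jx] = h2
            j[i, jx] = j2
            d[i, jx] = d2
            f[i, jx] = f2
            x1[i, jx] = x2
            cai[i, jx] = ca2


@njit(cache=True, nogil=True)
def gates_block(vm, R, pv, dt, r0, r1, c0, c1, m, h, j, d, f, x1):
    """Stage 1 of the staged (reference) step: gate updates at pre-step Vm."""
    use_j = pv[5] > 0.5
    shw = pv[7]
    for i in range(r0, r1):
        for jx in range(c0, c1):
            m2, h2, j2, d2, f2, x2 = gates_step(
                vm[i, jx], m[i, jx], h[i, jx], j[i, jx], d[i, jx], f[i, jx],
                x1[i, jx], R, dt, shw, use_j)
            m[i, jx] = m2
            h[i, jx] = h2
            j[i, jx] = j2
            d[i, jx] = d2
            f[i, jx] = f2
            x1[i, jx] = x2


@njit(cache=True, nogil=True)
def currents_block(vmp, wgt, istim, R, pv, dt, r0, r1, c0, c1,
                   vm_out, m, h, j, d, f, x1, cai):
    """Stage 2 of the staged step: currents, Cai and Vm from updated gates."""
    g_na = pv[0]
    e_na = pv[1]
    g_nac = pv[2]
    g_s = pv[3]
    inv_cm = 1.0 / pv[4]
    use_j = pv[5] > 0.5
    floor = pv[6]
    shw = pv[7]
    for i in range(r0, r1):
        for jx in range(c0, c1):
            w = wgt[i, jx]
            dv = (w[0] * vmp[i, jx] + w[1] * vmp[i, jx + 1] + w[2] * vmp[i, jx + 2]
                  + w[3] * vmp[i + 1, jx] + w[4] * vmp[i + 1, jx + 1]
                  + w[5] * vmp[i + 1, jx + 2]
                  + w[6] * vmp[i + 2, jx] + w[7] * vmp[i + 2, jx + 1]
                  + w[8] * vmp[i + 2, jx + 2])
            v2, ca2 = integrate_node(
                vmp[i + 1, jx + 1], m[i, jx], h[i, jx], j[i, jx], d[i, jx],
                f[i, jx], x1[i, jx], cai[i, jx], dv, istim[i, jx],
                g_na, e_na, g_nac, g_s, inv_cm, use_j, floor, shw, dt)
            vm_out[i, jx] = v2
            cai[i, jx] = ca2


@njit(cache=True, nogil=True)
def update_block_dv(vm, dvm, istim, R, pv, dt, r0, r1, c0, c1,
                    vm_out, m, h, j, d, f, x1, cai):
    """Fused ionic step with a precomputed diffusion-rate grid (scatter path)."""
    for i in range(r0, r1):
        for jx in range(c0, c1):
            v2, m2, h2, j2, d2, f2, x2, ca2 = cell_update(
                vm[i, jx], m[i, jx], h[i, jx], j[i, jx], d[i, jx], f[i, jx],
                x1[i, jx], cai[i, jx], dvm[i, jx], istim[i, jx], R, pv, dt)
            vm_out[i, jx] = v2
            m[i, jx] = m2
            h[i, jx] = h2
            j[i, jx] = j2
            d[i, jx] = d2
            f[i, jx] = f2
            x1[i, jx] = x2
            cai[i, jx] = ca2


@njit(cache=True, nogil=True)
def gather_diffusion(vmp, wgt, out, r0, r1, c0, c1):
    """dVm/dt from the 9-point stencil; each node reads its neighbourhood."""
    for i in range(r0, r1):
        for jx in range(c0, c1):
            w = wgt[i, jx]
            out[i, jx] = (
                w[0] * vmp[i, jx] + w[1] * vmp[i, jx + 1] + w[2] * vmp[i, jx + 2]
                + w[3] * vmp[i + 1, jx] + w[4] * vmp[i + 1, jx + 1]
                + w[5] * vmp[i + 1, jx + 2]
                + w[6] * vmp[i + 2, jx] + w[7] * vmp[i + 2, jx + 1]
                + w[8] * vmp[i + 2, jx + 2])


@njit(cache=True, nogil=True)
def scatter_diffusion(vmp, wgt, out):
    """dVm/dt by scattering each source's contribution into its neighbours.

    Iterates sources (including ghosts) in fixed row-major order and
    accumulates writes into the 9 targets each source touches -- the direct
    port of the neighbour-writing formulation.  Weights belong to the target
    node, matching the gather transform.
    """
    ny = out.shape[0]
    nx = out.shape[1]
    for i in range(ny):
        for jx in range(nx):
            out[i, jx] = 0.0
    for a in range(ny + 2):
        for b in range(nx + 2):
            src = vmp[a, b]
            for di in range(3):
                i = a - di
                if i < 0 or i >= ny:
                    continue
                for dj in range(3):
                    jx = b - dj
                    if 0 <= jx < nx:
                        out[i, jx] += wgt[i, jx][di * 3 + dj] * src
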