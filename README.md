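# cardiowave

A 2D cardiac electrical wave propagation simulator for studying action
potential conduction, spiral-wave (rotor) reentry and rotor breakup in
ventricular tissue — built for people who care both about the
electrophysiology and about how stencil kernels are organized.
`cardiowave` implements the monodomain reaction–diffusion model with
Beeler–Reuter membrane kinetics and the Drouhard–Roberge sodium current,
and exposes the classic kernel-optimization strategies for this workload
(scatter vs. gather stencils, structure-of-arrays layout, cache tiling,
row-parallel decomposition) as interchangeable, equivalence-tested CPU
backends.

## Model

The transmembrane potential Vm(x, y, t) on a rectilinear grid obeys

    ∂Vm/∂t = Dxx ∂²Vm/∂x² + 2 Dxy ∂²Vm/∂x∂y + Dyy ∂²Vm/∂y² + (I_stim − I_ion)/C_m

with no-flux boundaries. The diffusion tensor is diag(D_par, D_perp)
rotated by the fiber angle θ. The ionic current

    I_ion = I_Na + I_s + I_K1 + I_x1

uses the Drouhard–Roberge fast sodium current
I_Na = (g_Na m³ h + g_NaC)(Vm − E_Na) with g_Na = 15 mS/cm², E_Na = 40 mV,
and the Beeler–Reuter slow inward current
I_s = g_s d f (Vm − E_s), E_s = −82.3 − 13.0287 ln Cai, time-independent
potassium current I_K1 and time-activated outward current I_x1. Gates
follow Hodgkin–Huxley kinetics dg/dt = α(Vm)(1−g) − β(Vm) g, with all
rate constants shipped in a plain-text table
(`src/cardiowave/data/brdr_v1.params`). Space is discretized with a
9-point finite-difference stencil, time with explicit Euler under a CFL
guard. See `docs/methods.md` for the full account.

## Worked example

```python
import cardiowave as cw
from cardiowave.metrics import activation_map, conduction_velocity, apd
from cardiowave.simulation import make_protocol, run

params = cw.IonicParams.default()
rest = cw.find_rest_state(params)
print(f"rest Vm       : {rest.vm:.2f} mV")

times, vm, _ = cw.simulate_cell(params, dt=0.01, duration=500.0,
                                stim_amplitude=40.0, stim_duration=2.0)
print(f"AP peak       : {vm.max():.1f} mV")
print(f"APD90         : {apd(times, vm):.1f} ms")

cfg = make_protocol("plane_wave", cw.Grid2D(64, 64))
res = run(cfg)
am = activation_map(res)
cv = conduction_velocity(am, cfg.grid, row=32, x_range=(16, 56))
print(f"plane-wave CV : {cv*1000:.1f} cm/s")
```

prints

    rest Vm       : -84.76 mV
    AP peak       : 47.6 mV
    APD90         : 283.0 ms
    plane-wave CV : 56.8 cm/s

i.e. a −84.8 mV resting potential, a ~283 ms action potential, and a
plane-wave conduction velocity of ~57 cm/s at the default
D = 0.001 cm²/ms and 0.25 mm spacing — all in the physiological range for
ventricular muscle. `make_protocol("single_rotor")` configures the
cross-field S1–S2 protocol that induces a sustained spiral wave on a
192×192 sheet, with the S2 fired automatically when the center node
repolarizes through a threshold.

## Command line

    cardiowave run --protocol plane_wave --grid 64 --out out/
    cardiowave equivalence --grid 48 --backends reference,gather,scatter,tiled,parallel
    cardiowave tune --grid 64 --tiles 8x8,16x16,32x32,64x8
    cardiowave benchmark --grids 64,128,256 --backends gather --steps 100 --out bench.csv
    cardiowave fixtures --kind symmetric --grid 32 --seed 3 --out f.snap

`run` writes a probe trace (CSV), Vm snapshots (documented little-endian
binary format, see `cardiowave.io`), the resolved config, and a
`manifest.json` sufficient to reproduce the run. A nonzero exit code
signals numerical instability. Config files are flat `key = value` text;
the recognized keys are exactly the fields of `SimConfig`
(`nx, ny, dx, dy, theta, d_par, d_perp, dt, duration, backend, tile_x,
tile_y, workers, probe_x, probe_y, snapshot_every, seed, ca_speedup,
use_j_gate, params_file` and `stim.<n>.*` blocks); unknown keys are
errors, angles accept a `deg` suffix.

## Backends

| backend    | strategy                                                   |
|------------|------------------------------------------------------------|
| reference  | staged nested-loop passes (gates, currents+Vm, ghost refresh) |
| gather     | fused neighbour-update-free kernel: each node reads, writes itself |
| scatter    | per-source writes into 9 neighbours; kept as cross-check oracle |
| tiled      | gather over cache-sized blocks (block-size analogue)        |
| parallel   | gather over row strips on a thread pool                     |

All backends share one set of scalar kernels; the read-only family is
bit-identical by construction (each node is written once from pre-step
values), and `run_equivalence` verifies pairwise sup-norm agreement to
10⁻¹⁰ mV (10⁻⁹ for scatter) on every run it is asked to check.

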