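# Methods

## Model

`cardiowave` solves the 2D monodomain reaction–diffusion equation for the
transmembrane potential Vm(x, y, t) of a sheet of ventricular tissue:

    dVm/dt = Dxx Vxx + 2 Dxy Vxy + Dyy Vyy + (I_stim − I_ion) / C_m

with the membrane current I_ion given by the Beeler–Reuter ventricular
model in which the fast inward sodium current uses the Drouhard–Roberge
revision ("BRDR"): g_Na = 15 mS/cm², E_Na = 40 mV, Drouhard–Roberge m and h
kinetics, and the slow j inactivation gate dropped (it can be re-enabled
with `use_j_gate = true`, which restores the Beeler–Reuter j kinetics kept
in the constant table). The remaining currents are the Beeler–Reuter slow
inward current I_s (gates d, f; reversal E_s = −82.3 − 13.0287 ln Cai),
time-independent potassium current I_K1, and time-activated outward current
I_x1 (gate x1), plus a small background sodium conductance
g_NaC = 0.003 mS/cm² that keeps the rest state well defined. Intracellular
calcium follows dCai/dt = −10⁻⁷ I_s + 0.07(10⁻⁷ − Cai), floored at
10⁻¹⁰ mol/L so that ln Cai stays finite.

All gate rates are instances of one canonical form

    rate(V) = (c1 e^{c2 (V+c3)} + c4 (V+c5)) / (e^{c6 (V+c3)} + c7)  [1/ms]

whose coefficients ship in a versioned plain-text table
(`data/brdr_v1.params`). Rates with a removable 0/0 singularity (the
sodium activation opening rate; the (V+23)/(1−e^{−0.04(V+23)}) factor of
I_K1) carry their analytic limit and return it within 10⁻⁶ mV of the
singular point; everywhere else the closed form is evaluated directly.
The I_K1/I_x1 exponentials are algebraically factored through a single
e^{0.04 (V+53)}, which changes results only at the last-ulp level and is
applied identically on every code path.

## Discretization

Space: centered second differences on a rectilinear grid (row = y,
column = x, node (0,0) at the lower left), with the standard 4-corner
cross-derivative for the fiber-rotated tensor — a 9-point stencil
("the 8 neighbouring nodes and itself"). The tensor comes from rotating
diag(D_par, D_perp) by the fiber angle θ: Dxx = D_par cos²θ + D_perp sin²θ,
Dyy = D_par sin²θ + D_perp cos²θ, Dxy = (D_par − D_perp) sinθ cosθ. θ may
be a per-node grid, in which case weights are precomputed per node.

Boundaries: no-flux, via a ghost frame in which each ghost takes the value
of its adjacent interior node (even reflection across the domain face;
corners mirror diagonally). This face-centred reflection makes the
discrete operator exactly conservative for axis-aligned tensors
(Σ dVm = 0 to rounding), which is the property the tests assert; kernels
then run branch-free over the padded array (no boundary special cases in
the inner loops).

Time: explicit (forward) Euler with the canonical per-node order
gates → currents → Cai → Vm, gates evaluated at the pre-step Vm and the
ghost refresh preceding diffusion. Config validation enforces
dt ≤ 0.9 / (2(Dxx/dx² + Dyy/dy² + |Dxy|/(dx dy))) (a conservative CFL
bound for the 9-point scheme) and dt ≤ 0.02 ms (ionic stiffness cap).
The default dt = 0.01 ms. Gate updates are clamped to [0, 1]; the clamp is
a safety net — `DT_GATE_MAX = 7e-4` ms is the dt below which one Euler
update provably maps [0,1] into [0,1] for any Vm in [−120, +80] mV (the
worst case is the sodium deactivation rate at −120 mV), but along
physiological trajectories (Vm ≳ −90 mV) dt·(α+β) < 1 holds at 0.01 ms and
the clamp never engages.

Defaults dx = dy = 0.025 cm, D_par = 0.001 cm²/ms give a plane-wave
conduction velocity of ≈ 0.057 cm/ms (57 cm/s), in the physiological range
for ventricular muscle; CV scales as √D as theory predicts.

## Rest state

`find_rest_state` sets every gate to g_inf(V), Cai to the fixed point of
the calcium ODE (a rapidly converging inner iteration, since Cai feeds
back on I_s only through ln Cai), and solves I_total(V) = 0 by bisection
on [−100, −60] mV to |I_total| < 10⁻⁹ µA/cm². With the shipped constants
the rest potential is ≈ −84.8 mV and tissue initialized this way drifts by
< 10⁻³ mV over 100 ms.

## Backends and why they agree bit-for-bit

Every backend calls the same scalar jitted helpers for the per-node
update; they differ only in loop organization:

- **reference** — staged passes (gate pass, currents/Vm pass, serialized
  ghost refresh), the original nested-loop algorithm;
- **gather** — one fused pass; each node reads its padded neighbourhood
  and writes only itself (the neighbour-update-free transform that removes
  the need for atomics);
- **scatter** — a diffusion pass that accumulates per-source writes into
  the 9 targets (the direct port of the neighbour-writing form), then the
  ionic pass; retained as the cross-check oracle;
- **tiled** — the gather kernel over (tile_y, tile_x) blocks;
- **parallel** — the gather kernel over contiguous row strips on a thread
  pool (the kernels release the GIL).

Because each node's outputs depend only on pre-step values and are written
exactly once, the read-only family is bit-identical for any tile shape or
worker count; the tests assert 0 observed difference against a 10⁻¹⁰ mV
sup-norm budget over 1000 steps. The scatter backend may differ in
diffusion accumulation order and gets a 10⁻⁹ mV budget. State is stored
structure-of-arrays (one contiguous float64 grid per variable), the layout
the optimization study calls for.

## Stimulation protocols

Stimuli are rectangular current injections (µA/cm², depolarizing
positive). The default amplitude is 40 µA/cm² for 2 ms: strong enough to
capture partially recovered tissue, weak enough that a premature beat's
upstroke overshoot stays inside the ±(120/80) mV sanity bounds (at
60 µA/cm² a worst-phase S2 pushes a single cell past +80 mV).

- `plane_wave`: S1 strip of 5 columns at x = 0, isotropic D = 0.001.
- `single_rotor`: anisotropic preset (D_par = 0.001, D_perp = 0.0002,
  θ = 30°) with cross-field S1–S2: the S2 covers the lower-left quadrant
  and fires automatically when the domain-center node repolarizes through
  a configurable threshold (default −50 mV), latching exactly once. An
  auto-trigger replaces a hard-coded S2 time because the vulnerable window
  depends on the chosen constants.
- `breakup`: isotropic, θ = 0, larger default grid, same S1–S2.

### Reentry preset calibration

With the published BRDR kinetics the action potential lasts ≈ 281 ms, so
the spiral wavelength (CV × APD ≈ 16 cm) dwarfs any tractable grid. The
standard remedy in this model family is to accelerate the slow-inward
(d, f) gate kinetics by a constant factor; `IonicParams.ca_speedup`
multiplies those four rate functions. The single-rotor preset uses
ca_speedup = 6 (APD90 ≈ 110 ms), for which the cross-field S2 on a
192×192 grid (4.8 × 4.8 cm) produces a stable rotor whose period lets the
domain-center probe activate repeatedly within a 300 ms observation
window; the breakup preset pushes the factor to 8 (steeper effective
restitution) on a larger default grid (256×256) to promote wavebreak. In
this regime the preset produces sustained complex activity with recurring
transient wavebreak (episodes of up to ~4 simultaneous wavelets shed by a
meandering rotor) rather than fully developed fibrillation; decisively
multi-wavelet states in this model family need substantially larger
domains than are practical here. Sustained reentry is judged by two explicit criteria: at least one
excited node (Vm > −30 mV) at every snapshot in the 300 ms after S2, and
at least 3 distinct probe activations in that window (ruling out a single
decaying wave).

## Performance accounting

`SimResult` counts node updates exactly (steps × nx × ny) and times only
the stepping calls, so snapshot/probe bookkeeping and file I/O are
excluded from nodes-per-second figures, which are reported but never
asserted — they are hardware facts. `autotune_tiles` first proves every
tile candidate equivalent to the gather backend, then times each after a
warm-up. The first call in a process pays the JIT compilation cost;
benchmarks warm up before timing.

## What the tests do and do not show

The synthetic fixtures (impulse, plane, seeded random, mirrored random)
and the protocol presets exercise propagation, reentry and the numerical
contracts. They do not emulate real tissue heterogeneity, curved
geometries, deformation, or stochastic channel behaviour; passing tests
demonstrate the solver's internal consistency and the qualitative
electrophysiology of the BRDR sheet model (excitability, refractoriness,
anisotropic conduction, inducible spiral reentry), not patient-level
realism.

## Numerical choices and problem sizes

- Sanity bounds [−120, +80] mV: a Vm outside them aborts the run with the
  offending node/step and the last snapshot attached.
- Equivalence, conservation, symmetry and propagation checks run on grids
  of 48–64 nodes per side; the reentry check uses the 192×192 preset grid.
  These sizes were chosen so the full suite completes comfortably on one
  CPU while still resolving the relevant wavelengths (a plane wave front
  spans ~10 nodes at the default resolution).
- The recovery tail after an action potential is slow (the x1 gate
  deactivates with τ ≈ 230 ms near rest), so a cell returns to within
  1 mV of rest roughly 550 ms after a default stimulus.
- `seed` in the config is reserved: every shipped computation is
  deterministic; the field future-proofs noise experiments.

## Known limitations

Single ionic model (BRDR); 2D monodomain only (no bidomain, no 3D);
explicit Euler only (no Rush–Larsen or operator splitting); uniform D
magnitude (only the angle may vary per node); no phase-singularity
tracking or dominant-frequency analysis.
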