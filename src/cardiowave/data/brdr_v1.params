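# cardiowave ionic constant table  (format: key = value, '#' comments)
#
# Beeler-Reuter ventricular model with the Drouhard-Roberge revision of the
# fast inward sodium current: DR kinetics for the m and h gates with
# g_Na = 15 mS/cm^2 and E_Na = 40 mV, j gate dropped by default (the BR j
# kinetics are retained below for the optional use_j_gate = true setting);
# BR kinetics for d, f, x1 and the BR I_s, I_K1, I_x1 current formulations.
#
# Rate functions follow the canonical form
#   rate(V) = (c1*exp(c2*(V+c3)) + c4*(V+c5)) / (exp(c6*(V+c3)) + c7)   [1/ms]
# with an optional removable singularity (singular_v, singular_limit).

format_version = 1

g_na = 15.0
e_na = 40.0
g_nac = 0.003
g_s = 0.09
c_m = 1.0
use_j_gate = false
cai_init = 2e-7
cai_floor = 1e-10
singular_halfwidth = 1e-6

# --- sodium activation m (Drouhard-Roberge) ---
rate.m.alpha.c3 = 42.65
rate.m.alpha.c4 = -0.9
rate.m.alpha.c5 = 42.65
rate.m.alpha.c6 = -0.22
rate.m.alpha.c7 = -1.0
rate.m.alpha.singular_v = -42.65
rate.m.alpha.singular_limit = 4.090909090909091

rate.m.beta.c1 = 1.437
rate.m.beta.c2 = -0.085
rate.m.beta.c3 = 39.75

# --- sodium inactivation h (Drouhard-Roberge) ---
rate.h.alpha.c1 = 0.1
rate.h.alpha.c2 = -0.193
rate.h.alpha.c3 = 79.65

rate.h.beta.c1 = 1.7
rate.h.beta.c3 = 20.5
rate.h.beta.c6 = -0.095
rate.h.beta.c7 = 1.0

# --- slow sodium inactivation j (Beeler-Reuter; active only if use_j_gate) ---
rate.j.alpha.c1 = 0.055
rate.j.alpha.c2 = -0.25
rate.j.alpha.c3 = 78.0
rate.j.alpha.c6 = -0.2
rate.j.alpha.c7 = 1.0

rate.j.beta.c1 = 0.3
rate.j.beta.c3 = 32.0
rate.j.beta.c6 = -0.1
rate.j.beta.c7 = 1.0

# --- slow inward activation d (Beeler-Reuter) ---
rate.d.alpha.c1 = 0.095
rate.d.alpha.c2 = -0.01
rate.d.alpha.c3 = -5.0
rate.d.alpha.c6 = -0.072
rate.d.alpha.c7 = 1.0

rate.d.beta.c1 = 0.07
rate.d.beta.c2 = -0.017
rate.d.beta.c3 = 44.0
rate.d.beta.c6 = 0.05
rate.d.beta.c7 = 1.0

# --- slow inward inactivation f (Beeler-Reuter) ---
rate.f.alpha.c1 = 0.012
rate.f.alpha.c2 = -0.008
rate.f.alpha.c3 = 28.0
rate.f.alpha.c6 = 0.15
rate.f.alpha.c7 = 1.0

rate.f.beta.c1 = 0.0065
rate.f.beta.c2 = -0.02
rate.f.beta.c3 = 30.0
rate.f.beta.c6 = -0.2
rate.f.beta.c7 = 1.0

# --- outward activation x1 (Beeler-Reuter) ---
rate.x1.alpha.c1 = 0.0005
rate.x1.alpha.c2 = 0.083
rate.x1.alpha.c3 = 50.0
rate.x1.alpha.c6 = 0.057
rate.x1.alpha.c7 = 1.0

rate.x1.beta.c1 = 0.0013
rate.x1.beta.c2 = -0.06
rate.x1.beta.c3 = 20.0
rate.x1.beta.c6 = -0.04
rate.x1.beta.c7 = 1.0
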