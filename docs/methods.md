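# Methods

This note documents the models implemented in `dexsim`, their assumptions,
the numerical choices, and what the synthetic simulations do and do not
establish about real tissue.

## Encoding physics

Static-gradient spin-echo (SGSE) diffusion weighting is
b = (2/3) γ² g² τ³ with γ the ¹H gyromagnetic ratio
(2.6752218744×10⁸ rad s⁻¹ T⁻¹), g the static gradient (T/m) and τ the
half-echo time (ms); b is reported in ms/μm². Compartments are abstracted
as apparent diffusivities (ADCs): signal in site j attenuates as
exp(−b·ADC_j). This presumes barrier-limited exchange — each site is well
mixed on the encoding timescale — and deliberately excludes
localization-regime physics (sites whose structural length exceeds the
dephasing length ℓ_g are outside the model's scope). All computations are
SI internally with unit conversion centralized in `physchem`.

## Pump–leak model (PLM)

State: intracellular amounts of Na⁺, K⁺, Cl⁻. Algebraic closures at every
instant: volume from osmotic equality w = (n_Na + n_K + n_Cl + x_i)/c_o (water
permeability treated as effectively infinite), voltage from net charge
V = F(n_Na + n_K − n_Cl + z·x_i)/C_m. Passive fluxes use the
Goldman–Hodgkin–Katz form −P·A·φ(u)·(c_i − c_o e^{−u}) with
u = qFV/RT and φ(u) = u/(1−e^{−u}); a linear driving-force law is
available behind `flux_law="linear"`. Both vanish exactly at the Nernst
equilibrium. The pump extrudes 3 and imports 2 ions per cycle and is
first-order in intracellular Na⁺, so it self-limits in sodium-free media.

Defaults (package choices, exercised only qualitatively): spherical cell
of 1 pL, area 4.84×10⁻¹⁰ m², C_m = 1 μF/cm², permeabilities
P_Na : P_K : P_Cl = 0.1 : 1 : 0.2 ×10⁻⁶ m/s, T = 298 K, t_end = 2000 s.
The pump rate is calibrated by root-finding so the normal-media steady
state sits at −48 mV (±0.1 mV); steady state is declared when final volume
and voltage change by <10⁻⁴ relative upon a tenfold extension of the run.

Because the capacitive voltage relaxes on ~μs while volume equilibrates on
~10²–10³ s, the ODE system is stiff; it is integrated with LSODA
(rtol 10⁻⁸) rather than explicit stepping, and convergence is verified by
tolerance tightening (<0.1% change in final state). The baseline initial
condition closes electroneutrality and osmotic balance against the normal
bath ([Na]ᵢ = 12, [Cl]ᵢ = 10 mM, V₀ = −60 mV), and the same cell (same
x_i) is transferred into perturbed media so volume changes are comparable.

Perturbation battery: (i) normal media, pump off — unbounded Donnan
swelling, no steady state; (ii) +100 mOsm osmolyte — shrinkage and
hyperpolarization with the pump on, stable swelling without voltage
recovery with it off; (iii) NaCl → 256 mM uncharged osmolyte — similar
shrinkage and voltage for pump on/off (nothing to pump); (iv) NaCl →
128 mM Na-gluconate, pump off — full depolarization to 0 mV. These sign
patterns, not the percent magnitudes, are the asserted outcomes.

## Steady-state ECS fraction

Tissue total volume is fixed at w_tot (a placeholder for dural/ECM
constraints) and a small uncharged impermeant x_o = x_i/50 is trapped in
the ECS, which keeps f_o > 0 and smooth. Calibration: the reference cell
volume at (normal media, −48 mV) from w = (1−z)x_i/(c_o − 2Cl_o e^{FV/RT})
is assigned an initial ECS fraction f_o = 0.3, giving w_tot = w_ref/0.7.
The steady state solves

f_o = 1 − (1−z)x_i / { w_tot [c_o(s_o) − 2Cl_o e^{FV/RT} + x_o/(f_o w_tot)] },

with c_o(s_o) = Na_o + K_o + Cl_o + s_o. Multiplying by f_o gives
B f_o² + (C − B + A) f_o − C = 0 with A = (1−z)x_i/w_tot,
B = c_o − 2Cl_o e^{FV/RT}, C = x_o/w_tot; the root in (0, 1) is taken
(the larger root if two exist, continuous with the large-s_o limit), with
a damped-bisection fallback when B ≤ 0. Naive fixed-point iteration
oscillates at −10 mV, which is why the closed form is preferred.
x_i = 1 in arbitrary mol units: every downstream quantity depends only on
ratios. Defaults: z = −1, Cl_o = 132 mM, T = 298 K. The osmolyte grid for
sweeps is 0–150 mOsm (5-mOsm steps), chosen to cover the 0 and 100 mOsm
anchor conditions.

## Exchange signal simulation

Site order is (a, b, c) = (ECS, mobile ICS, restricted ICS). The 3XM rate
matrix couples a↔b and a↔c at k_t and b↔c at k_g, scaled by the partner
fractions so that columns sum to zero and detailed balance
k_ij f_i = k_ji f_j holds; eigenvalues are (0, f_a k_t + (f_b+f_c) k_g,
k_t). Defaults: k_t = 300 s⁻¹, k_g = 30 s⁻¹, f_b = f_c = (1−f_a)/2,
ADC = (1, 1, 0.1) μm²/ms, R1 = 1 s⁻¹ in all sites. Named ADC variants
change the mobile-ICS diffusivity (1.5 or 0.5) or make the ECS
diffusivity fraction-dependent (ADC_a = 1.7 f_o). Signals are the operator
product 1′·e^{−b₂D}·e^{−t_m(K+R₁)}·e^{−b₁D}·f via scipy's
scaling-and-squaring `expm` (K is not symmetric). Exchange and R2 during
the sub-millisecond encodings are off by default (τ ≪ 1/k, τ ≪ T2) but
can be enabled.

The CTMC oracle simulates particles jumping between sites at the rates
generated by K (i→j at −K[j,i]), weighting each by
e^{−b₁ADC(start)} · e^{−∫R1 dt} · e^{−b₂ADC(at t_m)}; it is an unbiased
estimator of the same observable and agrees with the matrix exponential
within Monte-Carlo error, providing an independent cross-check that is
never used as the implementation.

## DEXR fitting

Protocol: encodings (τ₁, τ₂) = (0.200, 0.735) ms (reference; b = 0.089,
4.435 ms/μm²) and (0.593, 0.580) ms (equal-b; 2.329, 2.179), mixing times
{0.2, 1, 2, 4, 7, 10, 20, 40, 80, 160, 300} ms. The reference decay is fit
with the biexponential (rates seeded from log-linear fits to the late and
early thirds; bounds w₁∈[0,1], rates∈[0,10⁵] s⁻¹; a few deterministic
fallback starts guard against local minima), divided out of the equal-b
signal, and the ratio fit with I₀e^{−t_m·AXR} + B (plain unweighted least
squares; constant input returns AXR = 0 flagged degenerate). Mixing times
are ms at the interface, seconds inside the fits.

Because b₁ of the reference cannot be zero on a static-gradient system,
the reference carries a small positive exchange-mode amplitude that the
biexponential absorbs and the division removes from the DEXR signal. A
consequence worth stating precisely: with that amplitude positive, the
DEXR ratio decays toward its plateau at an instantaneous rate everywhere
*below* the exchange eigenvalue, so two-site estimates land slightly
below the ground-truth k (measured 0.967–0.996·k across f_a; always
within 10%, the bounded property asserted in the tests). No correction is
applied. For the 3XM the estimate interpolates monotonically between k_g
and k_t as f_a goes 0 → 1; at the normal condition (f_o = 0.32) the
pipeline yields AXR = 136.6 s⁻¹ and at the depolarized condition
(f_o = 0.02) 35.6 s⁻¹ — the osmotic-condition dependence that motivates
the model. On 100 log-spaced mixing times (0.2–400 ms) the DEXR signal is
fit by a single rate with RMS < 1% of the signal range in all three
standard conditions: the 3XM does not by itself produce visibly
multiexponential exchange decay, because λ₂ and λ₃ are not dissimilar
enough.

## What the synthetic data does and does not show

The simulations are noiseless, use first-order exchange kinetics, fixed
compartment ADCs, uniform R1, and a single cell geometry; they emulate
the *mechanism* linking osmotic state → ECS fraction → AXR, not the full
heterogeneity of tissue (distributions of rates, non-Gaussian diffusion,
surface-to-volume changes, pressure nonlinearities, localization-regime
signal). Passing tests therefore establish internal mathematical
consistency and the qualitative mechanism, not quantitative agreement
with any particular measured tissue. A Gaussian-noise fixture
(`add_noise`) exists for robustness checks only; the reference outputs
are deterministic and bitwise reproducible.

## Numerical choices and degenerate inputs

Quadratic solve for f_o with tolerance 10⁻¹²; bisection fallback limited
to 200 iterations; `expm` on 3×3 matrices; least-squares with
xtol = ftol = 10⁻¹⁵; GHK voltage factor evaluated with a series branch
for |u| < 10⁻⁸ and exponent clipping at |u| = 60; monoexponential
reference data produces a degenerate but well-defined biexponential curve
(parameters reported fast-rate-first); f_o exactly 0 or 1 and empty or
non-increasing t_m grids are rejected with diagnostics.
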