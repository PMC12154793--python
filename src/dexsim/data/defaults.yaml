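# Default protocol and model parameters for the two-encoding SGSE DEXSY
# simulations.  Units: g in T/m, times in ms, rates in s^-1, ADC in um^2/ms,
# concentrations in mM, voltages in mV.
protocol:
  g_T_per_m: 15.3
  encodings:
    - {tau1_ms: 0.200, tau2_ms: 0.735}   # reference (low b1, high b2)
    - {tau1_ms: 0.593, tau2_ms: 0.580}   # equal-b exchange encoding
  tm_ms: [0.2, 1, 2, 4, 7, 10, 20, 40, 80, 160, 300]

exchange:
  k_t: 300.0    # transmembrane rate, ECS <-> both ICS sites
  k_g: 30.0     # geometric rate, mobile ICS <-> restricted ICS
  k: 300.0      # two-site model ground-truth rate
  R1: 1.0       # spin-lattice rate, all sites

adc_variants:
  baseline:      [1.0, 1.0, 0.1]
  fast_ics:      [1.0, 1.5, 0.1]
  slow_ics:      [1.0, 0.5, 0.1]
  fo_scaled_ecs: ["1.7*fo", 1.0, 0.1]

volume_model:
  z: -1.0
  Cl_o: 132.0
  fo_init: 0.3
  xo_ratio: 0.02      # x_o = x_i / 50
  T_K: 298.0
  V_normal: -48.0     # pump active
  V_depolarized: -10.0  # pump inhibited

media:
  normal:                 {Na_o: 128, K_o: 4, Cl_o: 132, s_o: 0,   g_o: 0}
  osmolyte_100:           {Na_o: 128, K_o: 4, Cl_o: 132, s_o: 100, g_o: 0}
  sucrose_substitution:   {Na_o: 0,   K_o: 4, Cl_o: 4,   s_o: 256, g_o: 0}
  gluconate_substitution: {Na_o: 128, K_o: 4, Cl_o: 4,   s_o: 0,   g_o: 128}
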