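grc:
  soma:
    capacitance_pF: 3.1
    g_leak_nS: 1.1
    e_leak_mV: -70.0
    g_na_nS: 300.0
    e_na_mV: 50.0
    g_kdr_nS: 100.0
    e_k_mV: -90.0
    ahp_increment_nS: 0.65
    ahp_tau_ms: 8.0
    v_shift_mV: 0.0
  gaba:
    kind: GABA_A
    tau_rise: 5.0
    tau_decay: 100.0
    peak_conductance: 0.075
    reversal: -75.0
    target_compartment: soma
goc:
  soma:
    capacitance_pF: 30.0
    g_leak_nS: 3.0
    e_leak_mV: -55.0
    g_na_nS: 2000.0
    e_na_mV: 50.0
    g_kdr_nS: 700.0
    e_k_mV: -90.0
    ahp_increment_nS: 40.0
    ahp_tau_ms: 16.0
    v_shift_mV: 18.0
  dend_capacitance_pF: 20.0
  dend_g_leak_nS: 8.0
  axial_g_nS: 8.0
  dendrite_length_um: 300.0
  e_leak_range_mV:
  - -60.0
  - -50.0
  ampa:
    kind: AMPA
    tau_rise: 0.03
    tau_decay: 0.5
    peak_conductance: 15.0
    reversal: 0.0
    target_compartment: dendrite
  nmda:
    kind: NMDA
    tau_rise: 5.0
    tau_decay: 100.0
    peak_conductance: 4.0
    reversal: 0.0
    target_compartment: dendrite
mg_block:
  mg_mM: 1.2
  k0_mM: 3.57
  vs_mV: 9.0
normalize_inhibition: 1.0
normalize_excitation: 1.0
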