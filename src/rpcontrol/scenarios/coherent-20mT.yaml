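name: coherent-20mT
description: >
  High-field coherent pathway control: return the pair to the singlet
  state at 1 us via the T+/- intermediate.  The packaged weights are a
  representative good parameter set from the bounded global search
  (the winning set is search-budget dependent).
mode: coherent
system:
  g_a: 2.000
  g_b: 2.000
  b0_mT: 20.0
  a_iso_MHz: 15.0
  j_MHz: 0.1
  k_s_per_s: 0.0
coherent:
  components:
    - {state: "T+-", q: 0.82}
    - {state: "S", q: 0.95}
control:
  amplitude_mT: 1.85
  t_f_us: 1.0
  output_step_ns: 0.25
  seed_kick_rad: 0.01
search:
  bounds:
    q_intermediate: [0.5, 0.9]
    q_final: [0.9, 1.5]
    amplitude: [0.1, 3.0]
  population: 50
  generations: 50
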