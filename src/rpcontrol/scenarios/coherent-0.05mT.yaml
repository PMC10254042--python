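name: coherent-0.05mT
description: >
  Geomagnetic-scale coherent pathway control: store population in the
  isolated T+alpha / T-beta states and return it to the singlet at 1 us.
  Weights are the published best set {q_S, q_T, A} = {0.93, 0.89, 1.1}.
mode: coherent
system:
  g_a: 2.000
  g_b: 2.000
  b0_mT: 0.05
  a_iso_MHz: 15.0
  j_MHz: 0.1
  k_s_per_s: 0.0
coherent:
  components:
    - {state: "T+a,T-b", q: 0.89}
    - {state: "S", q: 0.93}
control:
  amplitude_mT: 1.1
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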