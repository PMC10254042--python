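name: aniso-parallel-3.6mT
description: >
  Anisotropic selection: retain pairs whose hyperfine long axis is nearly
  parallel to the static field (q = 5 for beta 0-50 and 130-180 deg,
  q = -3 penalty for beta 60-120 deg).
mode: ensemble
system:
  g_a: 2.000
  g_b: 2.002
  b0_mT: 3.6
  hyperfine_mT: [1.2, 1.2, 1.8]
  j_MHz: 0.1
  k_s_per_s: 1.0e+6
ensemble:
  beta_step_deg: 10.0
  bands:
    "0-50": 5.0
    "60-120": -3.0
    "130-180": 5.0
control:
  amplitude_mT: 3.0
  t_f_us: 2.0
  output_step_ns: 0.5
  seed_kick_rad: 0.01
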