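name: iso-keep-3.6mT
description: >
  Isotropic retention at 3.6 mT: uniform sub-ensemble weights (q = 1)
  transfer the singlet-born powder homogeneously into long-lived
  T+alpha / T-beta-rich eigenstates, suppressing recombination.
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
  bands: null
control:
  amplitude_mT: 3.0
  t_f_us: 2.0
  output_step_ns: 0.5
  seed_kick_rad: 0.01
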