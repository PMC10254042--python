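# rpcontrol

Locally optimized radio-frequency magnetic field design for radical-pair
spin dynamics and reaction-yield control.

A radical pair (two electron spins + one spin-1/2 nucleus, Hilbert
dimension 8) recombines spin-selectively from its singlet state.  This
package designs RF waveforms `u(t)` with the "living for the day" local
optimization law

```
u(t) = A * Im <target | L_V | rho(t)>
```

which guarantees a monotone performance index, and supports two control
modes:

* **Sub-ensemble (anisotropic) control** — a powder of molecular
  orientations (Euler-angle grid, |sin beta| Jacobian) shares one RF
  field; per-orientation targets are the two Hamiltonian eigenstates with
  the largest T+alpha / T-beta character, and band-wise weighting factors
  `q_k` select (q > 0) or penalize (q < 0) orientation bands.  Singlet
  recombination enters through the Haberkorn anticommutator
  superoperator.
* **Coherent pathway control** — a *moving target* (a desired final
  combination of singlet/triplet projectors back-propagated under the
  field-free Liouvillian) steers a single system so the goal state is
  reached exactly at the target time, optionally via weighted
  intermediate states.  A small seeded genetic algorithm globally
  optimizes the weighting/amplitude meta-parameters
  `{q_intermediate, q_S, A}` within published bounds.

Integration is performed in the interaction picture of each static
Liouvillian (the drift is exact via eigendecomposition); the closed-loop
nonlinearity is re-evaluated at every integrator stage.  Spectral
diagnostics (FFT power spectra, Hann-window STFT, eigenvalue-difference
stick spectra) connect the optimized waveforms to the magnetic-resonance
transitions they exploit.

Note: the closed loop has an exact `u = 0` fixed point whenever the
initial state, targets and Hamiltonian share a symmetry under which the
drive operator is odd (always the case for a singlet-born pair with
symmetric targets).  A tiny reproducible antisymmetric "seed kick"
(`e^{-i angle (Sx_A - Sx_B)}`, second-order-negligible for the singlet
population) ignites the feedback; reference lab-frame integrators ignite
from round-off noise instead.

## CLI

Five model scenarios are packaged (`rpcontrol scenarios` lists them):
three 3.6 mT anisotropic-powder scenarios and two coherent scenarios at
20 mT and 0.05 mT.

```bash
rpcontrol run iso-keep-3.6mT --out runs/iso          # waveform.csv, trajectories.csv, summary.json
rpcontrol search coherent-20mT --pop 25 --gens 8 --seed 1 --out hist.csv
rpcontrol spectrum runs/iso/waveform.csv --scenario iso-keep-3.6mT --out runs/iso
```

Scenario YAML keys carry explicit units (`b0_mT`, `a_iso_MHz`, `j_MHz`,
`k_s_per_s`); custom scenarios can be run by passing a YAML path.

## Layout

| module | contents |
| --- | --- |
| `spin_core` | spin operators, Euler rotations, lab-frame/isotropic Hamiltonians, projectors, resonance lines |
| `liouville` | vectorization, commutator/Haberkorn superoperators, exact free propagation |
| `targets` | eigenstate-pair targets, performance index, moving targets |
| `optimizer` | closed-loop interaction-picture integrator (shared-field, single, and batched) |
| `ensemble` | beta grids, band weights, Jacobian powder averaging |
| `search` | real-coded GA + random-search baseline |
| `analysis` | FFT power spectrum, STFT, stick spectrum |
| `scenarios` | packaged configs, fixtures, runners, CLI backends |
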