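# Default run configuration (all units: kcal/mol, Å, fs, K)
fixture:
  variant: mg_b
  seed: 1
  n_waters: 24
calibration:
  reference_barrier: 18.0
  reference_reaction_free_energy: -2.2
  windows: 55
  steps_per_window: 3000
  tolerance: 0.15
  max_iterations: 15
  seed: 11
  initial_alpha: -4.5
  initial_coupling: 6.5
mapping:
  windows: 55
  steps_per_window: 3000
  seeds:
  - 1
  - 2
  - 3
  bin_width: 2.0
langevin:
  temperature: 300.0
  friction: 10.0
  timestep: 1.0
flood:
  radius: 6.0
  sweeps: 3000
  seed: 5
lra:
  n_configurations: 4
  steps_per_configuration: 2000
  seed: 7
kinetics:
  kcat: 12.4
  temperature: 300.0
  ph: 7.4
output_dir: results/run
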