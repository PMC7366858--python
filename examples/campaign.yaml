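seed: 1
states:
- GDP
- GTP
n_orientations: 3
equilibration_steps: 25000
n_modes: 10
mdenm:
  n_replicas: 8
  excitations_per_replica: 32
  delta_T: 10.0
  relaxation_steps: 2500
  timestep_fs: 2.0
  temperature: 300.0
  friction_ps: 1.0
  diversity_displacement: 1.0
  diversity_threshold: 1.65
md_control_runs: 1
analysis:
  contact_cutoff: 8.0
  hbond_state_threshold: 4.5
  min_reference: 100
write_pdb: true
write_dcd: false
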