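# Desk-scale demo pipeline configuration.
sequence: HWDDD
seed: 1
output_dir: pepmpc_out

# nanocluster geometry (gold core + cationic ligand monolayer)
n_core: 144
n_ligands: 60
chain_beads: 9
core_radius: 0.9        # nm

# analysis cutoffs
ligand_contact_cutoff: 3.0    # A, inclusive
docking_contact_cutoff: 3.5   # A, strict
cluster_cutoff_nm: 0.1

# synthetic bound-state stage (substitutes atomistic refinement)
n_refine_frames: 400
refine_dt: 10.0         # ps
n_patch_ligands: 4
stage_distances: [25.0, 17.0, 16.0]   # A
stage_durations: [0.5, 0.75, 1.0]     # ns (desk scale)

docking:
  n_runs: 4
  run_length: 0.5       # ns per run (desk scale; production: 500)
  n_record: 200
  start_separation: 35.0  # A (production protocol: 100)
  rng_seed: 1
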