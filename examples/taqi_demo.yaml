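# Demo: M.TaqI/TBTA-style mapping cohort on the bundled synthetic genome
# (39,937 bp with exactly 111 TCGA duplex sites, emulating the T7 map density).
genome_fasta: examples/t7like_synthetic.fasta
enzyme: M.TaqI
include_star: false
ligand: TBTA
simulation:
  n_molecules: 14
  length_mode: uniform
  length_bp_range: [23000, 36000]
  combing:
    stretch_mean: 1.59
    stretch_sd: 0.03
  fragmentation:
    mean_breaks: 0.0
  labelling:
    p_label: 0.7
    fp_rate_per_bp: null   # derived: false positives ~ 1/3 of all labels
    sigma_loc_nm: 10.0
  seed: 0
alignment:
  stretch_min: 0.60
  stretch_max: 0.65
  stretch_step: 0.002
  shift_step_bp: 25.0
  match_tol_bp: 50.0
  try_both_orientations: true
  min_labels: 5
histogram:
  bin_width_bp: 50.0
global_stretch: false
output_dir: fluorocode_out
seed: 1
verbosity: INFO
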