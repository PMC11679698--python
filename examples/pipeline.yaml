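# Full pipeline on a synthetic paired survey; swap the synth block for an
# inputs block (survey_a/survey_b/crust/dl_table CSV paths) to analyze real data.
synth:
  seed: 3
output_dir: scratch/demo_run
stages:
  comparison: true
params:
  seed: 3
  n_perm: 999
  msa_threshold: 0.5
  eigen_cut: 1.0
  loading_threshold: 0.5
  idw_k: 2.0
  cell_size: [65.0, 65.0]
  idw_elements: [Fe, Zn]
  crown_elements: [Fe, Cr]
  ring_edges: [1, 2, 3, 4, 5]
  alpha: 0.05
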