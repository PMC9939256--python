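# Default simulated pooled screen: 40-domain library, 2 donors x 3 replicates,
# CD4/CD8, antigen+/- conditions, serial stimulations sequenced at rounds
# 0/1/6/8.
mode: simulate
seed: 1
outdir: runs/default
library:
  n_domains: 40
  n_potent: 8
  n_inhibitory: 2
  jitter: 1.0
design:
  donors: [donor1, donor2]
  replicates: 3
  subsets: [CD4, CD8]
  conditions: ['antigen+', 'antigen-']
  timepoints: [0, 1, 6, 8]
  cells_per_sample: 100000
  read_depth: 1000000
  mfi0: 1.0e4
  sigma_log: 0.15
  dirichlet_mass: 200.0
  sigma_fit: 0.05
estimator:
  min_cells: 500
  pseudocount: 0.5
  max_mismatch: 2
  max_bc_mismatch: 1
  linkage: average
  cut_height: null
  alpha: 0.05
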