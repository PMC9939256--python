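# Reduced-size simulated screen for quick smoke runs and round-trip checks.
mode: simulate
seed: 1
outdir: runs/small
emit_fastq: true
fastq_depth: 400
library:
  n_domains: 12
  n_potent: 3
  n_inhibitory: 1
design:
  donors: [donor1, donor2]
  replicates: 2
  subsets: [CD4, CD8]
  conditions: ['antigen+', 'antigen-']
  timepoints: [0, 1, 6, 8]
  cells_per_sample: 20000
  read_depth: 50000
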