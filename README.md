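# carpool-screen

Analysis toolkit for **pooled CAR signaling-domain screens** read out by
FlowSeq (sort-seq): a library of chimeric antigen receptor (CAR) constructs
differing only in their intracellular signaling domain (ICD) is expressed in
primary CD4/CD8 T cells, repeatedly stimulated with antigen-bearing tumor
cells, FACS-sorted into fluorescence bins (proliferation dye, cytokines,
activation markers), and each bin is amplicon-sequenced. The package turns
those bin-level read counts into per-construct phenotypes, computes relative
expansion across serial stimulations, and integrates every assay into a
ranked, FDR-controlled hit table — together with a ground-truth simulator so
the entire chain is testable end to end without any external data.

It is aimed at computational biologists analyzing pooled FACS-seq screens
(CAR libraries, MPRA-style reporter sorts, any bin-sort-and-sequence design)
and at methodologists who need a screen generator with known truth.

## The estimator and the scoring chain

With `r_ib` reads for construct *i* in bin *b*, `R_b` total reads in the bin
and `N_b` sorted cells in the bin, the cells-weighted read fraction

```
w_ib = (r_ib / R_b) · N_b        f_ib = w_ib / Σ_b' w_ib'        C_i = Σ_b w_ib
```

reconstructs each construct's bin-fraction vector `f_i` (the multinomial
maximum-likelihood estimate within bins) and its effective cell count `C_i`;
measurements with `C_i < 500` are excluded. For CellTrace Violet (CTV),
whose fluorescence halves at each division (`mfi0·2^-d`), generation-aligned
gates map bins to division numbers, giving each construct's division
distribution and mean divisions. Percent-positive metrics sum `f_ib` above a
gate-boundary threshold.

Relative expansion is the library-frequency fold-change versus the
pre-stimulation baseline: counts are normalized by median-of-ratios size
factors, `log2FC_it = log2((n_it/s_t + ½)/(n_i0/s_0 + ½))`, centered on the
library mean. Scoring z-scores every metric within (assay, donor,
replicate, subset), combines z-scores per domain with Stouffer's method
(`Z = Σz/√k`), applies a one-sample z-test and Benjamini–Hochberg FDR, and
summarizes each domain by its average rank across assays, its hierarchical
cluster (average linkage on the combined-Z matrix) and PCA coordinates.

## Worked example

```bash
python analysis/01_simulate_screen.py
python analysis/02_flowseq_phenotypes.py
python analysis/03_relative_expansion.py
python analysis/04_score_hits.py
```

simulates the default screen — 40 domains (8 potent, 2 inhibitory), 2 donors
× 3 replicates × CD4/CD8 × antigen±, sequenced at stimulation rounds
0/1/6/8 — then reconstructs phenotypes, expansion and the hit table. The
last script prints (seed 7):

```
top 10 by average rank:
  ICD01    rank   3.0  Z  11.70  q 2.70e-30  true class: potent
  ICD27    rank   3.3  Z  11.34  q 1.07e-28  true class: potent
  ...
8/8 potent truths in the top 10; 27 domains significant at q < 0.05
```

i.e. every simulated potent domain lands in the top 10 by average rank with
q far below 0.05, and `02_flowseq_phenotypes.py` reports the division-number
recovery (`Spearman rho(true, estimated) = 0.984` under full sequencing
overdispersion). Summary tables land in `results/`.

The same pipeline is scriptable through a config file:

```bash
carpool all --config configs/default.yaml --outdir runs/demo
```

with stages `simulate | count | quantify | expand | score | report` runnable
independently; `count` consumes FASTQ (real data, or simulated FASTQ via
`emit_fastq: true`) through dual-index demultiplexing, adapter trimming and
bounded-Hamming read assignment.

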