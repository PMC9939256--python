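# Methods

## The generative model

The simulator (`carpool.simulate`) is phenomenological: each library member
(`DomainTruth`) carries latent distributions for the quantities the screen
estimates, with no mechanistic signaling model underneath.

**Divisions.** One 3-day stimulation round allows up to 3 divisions; a
construct's per-round division profile is Binomial(3, p) with p ≈ 0.65 for
potent, 0.40 for intermediate and 0.25 for inhibitory domains (means
1.95 / 1.20 / 0.75 divisions per round, clipped to p ∈ [0.22, 0.80]),
realistic for short-horizon dye-dilution assays where even poorly
costimulated CARs divide through CD3ζ alone. Profiles are stored over
d = 0..8; D_max = 8 is the dye's resolution limit. Antigen-free profiles
interpolate between a floor (p = 0.08) and the stimulated profile with
weight `tonic_level` ∈ [0, 1], the construct's antigen-independent activity.

**Fluorescence.** CTV is `mfi0 · 2^-d · exp(ε)`, `ε ~ N(0, σ_log²)` with
`mfi0 = 10⁴` a.u. and `σ_log = 0.15` natural-log units (≈ 0.065 decades).
That noise level keeps adjacent generation peaks resolvable — the premise of
discrete division counting and of the D_max rationale; at ≈ 0.11 decades the
±half-generation gates would misassign ≈ 17% of cells and edge truncation
alone would bias mean-division estimates by up to ~0.09. Cytokine channels
(IL-2, IFN-γ) are lognormal, background ln-mean 5.3 (≈ 200 a.u., SD 0.7)
plus a class-dependent stimulated lift (≈ +2.2 potent, +1.2 neutral, +0.4
inhibitory, natural log); CD69 is a two-component lognormal mixture with
mixing weight `activation_prob`. Antigen-free parameters again interpolate
via `tonic_level`.

**Expansion.** Frequencies evolve multiplicatively:
`freq_{t+1} ∝ freq_t · fitness · exp(η)`, `η ~ N(0, σ_fit²)`, σ_fit = 0.05
per round; baseline is equimolar with lognormal pooling jitter (σ = 0.05).
Per-round fitness is ≈ 1.18 (potent), 1.00 (neutral), 0.88 (inhibitory) with
a small CD8 advantage (ln-shift 0.03 ± 0.03 across domains, so most — not
all — domains expand more in CD8). Antigen-free fitness is damped toward 1
in proportion to `tonic_level`.

**Sorting and sequencing.** Gates are half-open `[lo, hi)` in log10
fluorescence; out-of-gate cells are discarded and counted. CTV gates sit at
inter-generation midpoints `mfi0·2^-(d±½)` (4 bins, divisions 0–3), so each
gate holds exactly one generation peak and the bin→division map is well
posed. Reads per bin are Dirichlet-multinomial with concentration mass 200:
read fractions are unbiased for cell fractions but carry an effective sample
size of ~200 per bin regardless of depth, emulating PCR amplification
noise. `overdispersion=inf` gives the plain multinomial limit. Read depth
defaults to 10⁶ per bin sample.

**Donor structure.** Each donor gets (a) global channel shifts (cytokine
ln-mean SD 0.30, activation logit SD 0.20) that within-donor z-scoring must
cancel, and (b) per-(donor, domain) interaction jitter — an exponential tilt
of the division profile (θ SD 0.08), cytokine ln-mean SD 0.15, activation
logit SD 0.20, ln-fitness SD 0.02 — the biological noise the meta-combination
averages over. `simulate_screen(..., donor_variability=0)` switches (b) off,
making domains exchangeable across donors; the null-calibration experiment
uses this, since its premise is that domains are identical in every respect.

## Estimators and tests

The sort-seq reconstruction `w_ib = (r_ib/R_b)·N_b` is the multinomial MLE
of the cells per construct within each bin; the gate log-midpoint is the
bin's representative value (unbiased under a locally flat density, exact for
generation-aligned gates). The 500-cell filter uses strict `<` ("fewer
than" 500), and filtered measurements are missing everywhere downstream —
they shrink Stouffer's k and are imputed as 0 (the library average on the
z-scale) only inside clustering/PCA distance computations. No smoothing is
applied across bins by default; a Dirichlet pseudocount flag exists for very
low depth.

Size factors are median-of-ratios with the geometric-mean reference over
constructs positive in all samples, falling back to total-count scaling
(logged) otherwise; the 0.5 pseudocount before log2 bounds dropout
fold-changes without masking strong depletion. The CD8/CD4 contrast is a
Wald z on the difference of replicate means with pooled subset SEs. The
longitudinal signal is summarized by a per-replicate OLS slope of
library-relative log2FC against round, combined across replicates by
mean/SE — a deliberately simple trend statistic rather than a full
autocorrelated mixed model, which is outside this package's scope.

In the scoring chain, z-scores are computed across domains within each
(assay, donor, replicate, subset) group with sample SD (n−1); a
zero-variance group yields zeros with a warning. Group normality is checked
by Anderson–Darling (advisory only, logged). Stouffer combination is
unweighted; the per-domain overall Z combines the per-(assay, subset)
combined Zs with equal weight, keeping each assay's evidence on equal
footing regardless of its replicate count. Families for BH adjustment are
per analysis (the 40-domain hit test; the 40-domain CD8/CD4 test). The
Wilcoxon rank-sum test enumerates all label reassignments exactly for
n ≤ 12 and otherwise uses a tie-corrected normal approximation with
continuity and Edgeworth kurtosis corrections (fourth cumulant
`−n_x n_y (N+1)(n_x²+n_y²+n_x n_y+N)/120`), which keeps it within ~0.002 of
the exact p even at 6+6. The repeated-measures ANOVA decomposes sums of
squares into a between-donor stratum and a within-donor stratum carrying
domain, day and their interaction against the within residual, for balanced
complete designs only; a constant response reports F as NaN with a note.
Clustering is average-linkage on Euclidean distances of the combined-Z
matrix (configurable); flat clusters cut at 0.7 × the maximum merge height
by default. PCA centers and unit-scales columns, drops zero-variance
columns, imputes missing entries with column means, and fixes signs so each
component's largest-magnitude loading is positive.

## Validation experiments and their sizes

`carpool.validation` defines the recovery experiments used by both the test
suite and `scripts/acceptance.py`:

- **Division-estimator consistency** — one CTV FlowSeq sample of the default
  40-domain library, 10⁴ cells/construct, 10⁶ reads in the multinomial
  (infinite-concentration) limit; compared per construct against the drawn
  cells' true mean divisions. This isolates estimator bias; amplification
  overdispersion is exercised by the other experiments.
- **Hit recovery** — 20 complete default screens (2 donors × 3 replicates ×
  2 subsets × antigen±, 10⁵ cells and 10⁶ reads per sample, full donor
  variability), scored end to end.
- **Null calibration** — 200 screens of an all-identical library at reduced
  size (2 donors × 2 replicates × 2 subsets, antigen+ only, rounds 0 and 8,
  5·10⁴ cells and 5·10⁴ reads per sample), checking the BH q < 0.05 fraction
  and KS uniformity of the combined p-values.
- **Expansion recovery** — a single construct at fitness 1.1/round against a
  neutral background, 8 rounds, 3 replicates, abundance measured as
  multinomial samples of 10⁵ cells (the expansion module's input contract),
  against the closed form 8·log2(1.1) ≈ 1.100. The SE pools the
  across-replicate variance over all 40 constructs, which share one noise
  model by construction, so the 2·SE comparison has ~80 degrees of freedom
  rather than 2. Fitness ordering uses the default library over 6 replicate
  cultures.

## What the simulation does and does not show

The generator reproduces the statistical structure of a pooled bin-sort
screen — compositional frequencies, finite sorted-cell counts,
overdispersed amplicon counts, donor/replicate hierarchy, filter-induced
missingness — so passing tests demonstrate that the estimators and the
scoring chain recover known parameters under that structure and stay
calibrated under the null. They do not validate the biology: phenotype
distributions are phenomenological (no signaling model, no exhaustion
dynamics, no cell-cycle/division-time coupling), division and fluorescence
noise are independent across cells, sorting is perfect within gates (no
doublets, purity loss or instrument drift), and PCR noise is a single
Dirichlet mass rather than a cycle-dependent process. Real screens also
violate balance (dropout donors, unequal replicates) more aggressively than
the generator does.

## Known limitations

- The division deconvolution requires generation-aligned gates and errors
  out otherwise; there is no general deconvolution for arbitrary layouts.
- Read assignment is global bounded-Hamming (no indel handling); it is exact
  for the simulated amplicons and for references at pairwise distance
  ≥ 2·max_mismatch+1, which the reference validator checks.
- `rm_anova` handles balanced complete designs only.
- With two donors, per-(donor, domain) interaction variance is estimated
  from k = 2 effective units per assay; the combined Z treats measurements
  within a donor as independent, which mildly overstates evidence when
  interactions are large — visible in the simulator if `donor_variability`
  is raised well above its default.
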