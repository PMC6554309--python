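# Methods

## The question and the statistics

Given gene-level RNA-seq counts for two groups of samples, the package
asks, per chromosome, whether the *direction* of expression change is
spatially organised: do up-regulated (and down-regulated) genes sit
next to each other more than a random arrangement of the same fold
changes would produce?

With genes ordered by chromosomal position and `h_i` the log2 fold
change of gene *i* (group B over group A), the two test statistics are
the flip count `F = Σ 1[sign(h_i) ≠ sign(h_{i−1})]` and the energy
`E = Σ_i h_i·h_{i−1} + h_i·h_{i+1}` (out-of-range neighbours contribute
zero, so `E = 2·Σ h_i·h_{i+1}`). F ignores magnitudes entirely; E
weights agreement between neighbours by effect size. Both are compared
to the distribution obtained by permuting the order of the same `h`
values along the chromosome — a conditional null that keeps the
fold-change *values* fixed and randomises only their arrangement.

### Null calibration

Calls are directional: flips significant iff `z_F < −2`, energy iff
`z_E > +2`, where z uses the permutation mean and SD. The 2-SD rule is
conventionally quoted as a 4.55% false-positive rate (the two-sided
normal tail); because each call is one-directional the realised null
rate is ≈ 2.3% per metric, which the type-I-error simulation in the
test suite confirms. We keep the one-directional rule because only the
"fewer flips / more energy" direction indicates clustering.

The flips permutation null is never trusted on faith: `F = R − 1` with
R the Wald–Wolfowitz run count over `n₊` positive and `n₋` negative
signs, so `E[F] = 2n₊n₋/N` and
`Var[F] = 2n₊n₋(2n₊n₋ − N)/(N²(N−1))`. The permutation engine is
tested against these closed forms at several sign compositions. The
permutation-null mean of the energy likewise matches its exchangeable
expectation `2(S₁² − S₂)/N` with `S₁ = Σh`, `S₂ = Σh²`.

Zero fold changes (measure-zero for continuous data, possible with
pseudocounted discrete data) inherit the preceding gene's sign; a
leading zero counts positive. This convention is explicit and tested
rather than silent.

Chromosome-level nulls use sampling *without* replacement (uniform
random permutations via Fisher–Yates); permutation streams are spawned
per chromosome from a single scan seed in sorted chromosome order, so
results are reproducible and independent of evaluation order. Default
100,000 permutations; tests and simulations use 500–2,000, which is
ample for a 2-SD rule based on the null's first two moments.

## From counts to the profile

* **Size factors** are median-of-ratios: `factor_s = median_g
  (count_gs / geomean_g)` over genes with all-positive counts, rescaled
  to geometric mean 1. Passing spike-in ids as the reference yields
  absolute (per-cell) factors.
* **Expression cutoff.** Mean RPKM per gene (library size over
  non-spike genes) is log2-transformed; a Gaussian KDE locates the main
  density mode μ̂ and the upper half-width at `e^{−1/2}`·peak gives σ̂
  (mirrored about the mode so a silent-gene mode on the left cannot
  contaminate it). The KDE is oversmoothed (1.5× Scott's factor) to
  suppress mode wobble and the bandwidth is deconvolved from σ̂
  (`σ̂² = width² − bw²`). Genes with log2 mean RPKM above `μ̂ − 3σ̂`
  are "expressed". The estimator is intentionally simple; its sampling
  error is a few tenths of a log2 unit at ~5,000 genes, which is
  immaterial for a −3σ threshold.
* **Fold changes.** `h_g = log2[(mean_B + c)/(mean_A + c)]` over
  normalized counts with pseudocount `c = 0.5`. This is a deliberate,
  documented simplification relative to shrinkage-based differential
  expression estimators: the clustering statistics consume only the
  sign and relative magnitude of `h`, and an unshrunken estimator keeps
  the permutation null exact. Genes in a flagged excluded region (the
  duplicated interval; its strong common dosage signal would trivially
  drive clustering) stay in the profile for plotting but never enter
  the statistics. Gene order is by (start, end, id); position is the
  gene midpoint; strand is ignored.
* **Strata.** Expression strata are half-open: low [0.1, 10), medium
  [10, 100), high [100, ∞) mean RPKM — boundary values assign upward.
  Stratified fold-change comparisons use the two-sided Mann–Whitney U
  (asymptotic, tie-corrected).
* **Normalization comparison.** The global mRNA-content shift is
  `mean(FC_abs)/mean(FC_rel) − 1` over endogenous genes, where the two
  FC sets differ only in the size-factor reference (spike-ins vs all
  genes); per-stratum shifts detect skew toward low- or high-expressed
  genes.

## Domains and boundary alignment

A domain is a maximal run of ≥ 2 adjacent same-sign expressed genes.
Gene-level data cannot resolve a regulatory boundary below the
intergenic scale, so a domain limit is the midpoint between the two
flanking genes' midpoints; at a profile end the terminal gene's own
start/end is used. Boundaries are oriented (start/end), and a feature
within the ±2.5 Mb window gets a positive distance when it lies toward
the domain interior (downstream of a start, upstream of an end); exact
zeros count as interior. Interval tracks (LADs, replication domains)
contribute both edges as boundary points.

The relative-distance distribution is summarised by a Gaussian KDE with
the nrd0 bandwidth `0.9·min(SD, IQR/1.34)·n^{−1/5}` evaluated on a
512-point grid spanning the data range ± 3 bandwidths — matching the
default behaviour of R's `density()`, against which the implementation
is cross-checked on a frozen fixture. Identical distances fall back to
a positive bandwidth floor. The package reports curves, not enrichment
p-values: the appropriate null (feature placement) is study-specific.

## The synthetic-data generator

The generator exists so that every downstream stage is testable with
known ground truth; its defaults encode the study conditions the
analysis targets.

* **Geometry.** 20 chromosomes × 500 genes; gamma gene lengths (mean
  20 kb) and exponential intergenic gaps (mean 80 kb) tile each
  chromosome without overlap (≈ 50 Mb per chromosome).
* **Groups and dosage.** 4 control vs 5 duplicated samples; a 23 Mb
  duplicated interval (default chr16:10–33 Mb, ≈ 230 genes) whose genes
  get a 1.5× group-B effect — the three-copy expectation.
* **Counts.** `count_gs ~ NB(μ_gs, α)` with variance `μ + α·μ²`,
  α = 0.05 (typical inbred-replicate bulk RNA-seq); Poisson at α = 0.
  `μ_gs = depth_s · basemean_g · effect_gs · exp(noise_gs)`, basemeans
  log-normal (ln-scale mean 3.0, SD 1.2 → ~4 decades of expression),
  library sizes uniform on [8, 12] million.
* **Co-regulation.** Consecutive genes form blocks of 10 (~1 Mb, a
  TAD-like scale). The log-noise of gene g in sample s is
  `σ·(√ρ·b_{B(g),s} + √(1−ρ)·e_{gs})` with the block factor `b` shared
  within a block, giving same-block fold-change correlation ≈ ρ before
  counting noise. σ (`sample_noise_log_sd`, ln units) defaults to 0.15,
  a realistic biological CV for replicate cultures; ρ defaults to 0.5 —
  co-regulation within contact domains is the mechanism under study, so
  the default genome is non-null. Tests that need a null set ρ = 0
  explicitly.
* **Spike-ins.** Fixed per-cell abundances (group effect exactly 1 in
  the emitted truth); sequencing depth multiplies spike-ins and
  endogenous RNA alike, while `global_inflation` multiplies only
  group-B endogenous transcripts — separating depth from mRNA content
  is precisely what makes absolute normalization informative.
* **Tracks.** TAD boundaries are the true block edges ± uniform
  jitter; CTCF sites are TAD boundaries plus an equal number of uniform
  background sites; LADs merge pairs of adjacent blocks (boundaries a
  subset of TAD boundaries, hence fewer); replication domains are an
  independent random segmentation.
* **Reproducibility.** Each operation draws from its own RNG stream
  spawned from the config seed (annotation/counts/tracks), so any stage
  can be regenerated in isolation, bit-identically.

What the generator does **not** emulate: read-level sampling (FASTQ),
sequence content, isoforms, GC/length biases, batch structure, or
single-cell sparsity. Passing tests therefore demonstrate correctness
of the statistics and pipeline under the stated generative model, not
robustness to every artefact of real libraries.

## Problem sizes and numerical choices

Simulation-based tests use 4–10 chromosomes of 120–300 genes with
500–2,000 permutations, and the calibration runs use 1,000 null
chromosomes of 200 genes at 2,000 permutations — sizes chosen so the
binomial/Monte-Carlo error of each check is several times smaller than
the effect it tests. Chromosomes with fewer than 3 expressed
non-excluded genes are skipped with an explicit reason; degenerate
permutation nulls (all signs equal → SD 0) produce a flagged no-call,
never a silent significance. Loess smoothing (span 0.75, local linear,
tricube weights, no robustness iterations) is display-only.

## Known limitations

* The fold-change estimator is unshrunken; very low counts produce
  noisy `h` that the expression cutoff, not shrinkage, must control.
* The expression-cutoff fit assumes a dominant unimodal expressed
  component in log2 RPKM; strongly non-Gaussian expressed modes bias σ̂.
* The 2-SD rule is per chromosome; no genome-wide multiplicity
  correction is applied beyond it, by design.
* Boundary alignment reports densities only; enrichment significance
  requires a feature-placement null outside the package's scope.
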