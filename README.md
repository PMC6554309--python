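# geddscan

Statistical detection of **gene expression dysregulation domains
(GEDDs)** — chromosomal regions in which differentially expressed genes
change in the same direction — from bulk RNA-seq count data, together
with a synthetic-data generator that reproduces the structure such
analyses assume (trisomic dosage segments, TAD-like co-regulation
blocks, ERCC-style spike-ins).

## Who this is for

Transcriptomics researchers asking whether the up/down pattern of
expression changes along a chromosome is more spatially clustered than
chance — for example in aneuploidy models, where a dosage-imbalanced
segment may (or may not) reorganise expression genome-wide — and
methodologists who need a null-calibrated, fully simulatable testbed for
such claims.

## The statistics

For each chromosome, order the expressed genes by position and let
`h_i` be the log2 fold change of gene *i* between two conditions. Two
statistics quantify spatial clustering of the signs of `h`:

* **Flips** — the number of adjacent sign changes,

  `F = Σ_i 1[ sign(h_i) ≠ sign(h_{i−1}) ]`.

  Clustering of same-direction genes *depresses* F.

* **Energy** — a spatial-correlation measure,

  `E = Σ_i ( h_i·h_{i−1} + h_i·h_{i+1} )`,

  with out-of-range neighbour terms contributing zero. Clustering
  *raises* E, weighted by the magnitude of the changes.

Both are referred to a permutation null: the order of the genes on the
chromosome is randomly permuted (default 100,000 times), and a
chromosome is called significant when F lies more than 2 permutation
SDs *below* the null mean, or E more than 2 SDs *above* it. The flips
null has a closed form via the Wald–Wolfowitz runs test
(`E[F] = 2·n₊·n₋/N` with F = runs − 1), which the package uses as an
independent analytic oracle for its permutation engine.

Two controls probe what a positive result means:

* **Balanced relabeling** — samples are re-split into two sides that
  each contain equal numbers of both true genotypes, eliminating the
  genotype effect (with 4 + 4 samples and 2 of each per side there are
  exactly 18 distinct such comparisons). Clustering that survives
  relabeling is driven by sample-to-sample co-regulated variation, not
  genotype.
* **Spike-in (absolute) normalization** — comparing fold changes under
  spike-in-referenced and median-of-ratios size factors measures any
  global mRNA-content shift and its skew across expression strata.

Finally, domains are called as maximal runs of ≥ 2 adjacent same-sign
expressed genes, with boundaries placed half way between the flanking
opposite-sign genes, and their boundaries are compared with chromatin
feature tracks (TAD/LAD/replication-domain boundaries, CTCF sites) via
Gaussian kernel densities of signed relative distances in a ±2.5 Mb
window.

## Worked example

```python
import geddscan as g

cfg = g.SimulationConfig(
    n_chromosomes=4, genes_per_chromosome=120, group_sizes=(4, 4),
    duplicated_interval=("chr2", 1_000_000, 7_000_000),   # 1.5x segment
    block_correlation=0.6, sample_noise_log_sd=0.25, seed=3,
)
ann = g.make_annotation(cfg)
counts, truth = g.simulate_counts(ann, cfg)
profile = g.fold_change_profile(counts, ann, groups=("WT", "Dp"))
scan = g.scan_genome(profile, n_permutations=2000, seed=1)
print(scan.table[["chrom", "n_genes", "flips", "flips_z", "energy_z",
                  "flips_sig", "energy_sig"]].round(2).to_string(index=False))
dup = profile.data[profile.data.gene_id.isin(truth.duplicated_genes)]
print(f"mean linear fold change over duplicated genes: {(2**dup.h).mean():.3f}")
```

prints

```
chrom  n_genes  flips  flips_z  energy_z  flips_sig  energy_sig
 chr1      120     46    -2.55      4.08       True        True
 chr2       58     21    -1.80      1.89      False       False
 chr3      120     32    -4.55      4.81       True        True
 chr4      120     33    -4.82      5.43       True        True
mean linear fold change over duplicated genes: 1.381
```

With block co-regulation at ρ = 0.6, three of four chromosomes show
significantly depressed flips and elevated energy — clustering is
detected even though only chr2 carries a genotype effect. chr2 itself
has fewer testable genes (the duplicated interval is excluded from the
statistics) and does not reach 2 SDs here. The duplicated genes'
mean fold change estimates the planted 1.5× dosage; with only ~6
co-regulation blocks spanning the segment, this one draw sits at 1.38
(the block-shared noise makes the effective sample size the number of
blocks, not the number of genes).

The same pipeline is scriptable from the shell:

```bash
geddscan simulate --outdir data --seed 3
geddscan profile  --counts data/counts.tsv --design data/design.tsv \
                  --annotation data/annotation.bed --group-a WT --group-b Dp \
                  --out profile.tsv
geddscan scan     --profile profile.tsv --n-perm 100000 --seed 1 --out scan.tsv
geddscan switch   --counts data/counts.tsv --design data/design.tsv \
                  --annotation data/annotation.bed --per-side 2 --out switch.tsv
geddscan domains  --profile profile.tsv --tads data/tad_boundaries.bed --out domdir
geddscan report   --scan scan.tsv --switch switch.tsv --profile profile.tsv --out report
```

## Layout

| module | contents |
| --- | --- |
| `geddscan.io` | annotation (BED6/GTF) and count/design readers, validation |
| `geddscan.expression` | RPKM, expression cutoff, size factors, fold-change profiles, strata, normalization comparison |
| `geddscan.stats` | flips, energy, permutation nulls, per-chromosome tests, genome scan |
| `geddscan.relabel` | balanced relabeling enumeration and relabeling scans |
| `geddscan.domains` | domain calling, boundary tracks, relative distances, KDE |
| `geddscan.simulate` | synthetic annotations, NB counts, AR(1) profiles, feature tracks |
| `geddscan.report` / `geddscan.cli` | Loess curves, figures, summaries, `geddscan` CLI |

See `docs/methods.md` for the model, parameter and calibration details.
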