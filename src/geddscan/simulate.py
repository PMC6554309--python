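"""Synthetic RNA-seq data with known spatial structure.

Generates gene annotations, negative-binomial count matrices for two
genotype groups, directly parameterised fold-change profiles, and
chromatin-feature boundary tracks, all with the statistical structure
the downstream analysis assumes:

* a contiguous "duplicated" (three-copy) interval expressed at a
  configurable dosage ratio (1.5 for trisomy) in group B;
* block-structured co-regulation: multiplicative log-normal noise
  shared by consecutive genes within TAD-like blocks, inducing a
  tunable correlation between the fold changes of same-block genes;
* optional spike-in species at a fixed, library-size-independent
  abundance per sample (absolute normalization reference);
* an optional global inflation of all group-B endogenous transcripts
  (elevated total mRNA per cell);
* feature tracks (TAD/CTCF/LAD/replication-domain boundaries) aligned
  to the true co-regulation blocks.

Every generated dataset is accompanied by a :class:`SimulationTruth`
recording the ground-truth parameters for recovery tests. Each
operation uses its own RNG stream spawned deterministically from the
config seed (stream 0: annotation, 1: counts, 2: tracks), so each stage
is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .domains import BoundaryTrack
from .expression import FoldChangeProfile
from .io import SPIKE_IN_CHROM, CountMatrix, GeneAnnotation

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "make_annotation",
    "simulate_counts",
    "simulate_signed_profile",
    "make_feature_tracks",
    "write_dataset",
]

_STREAM_ANNOTATION = 0
_STREAM_COUNTS = 1
_STREAM_TRACKS = 2


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design the analysis targets: ~20
    chromosomes of ordered genes, 4 wild-type vs 5 duplicated samples,
    a 23 Mb three-copy interval expressed at 1.5x, NB dispersion
    (variance = mu + dispersion * mu^2), and TAD-like blocks of
    co-regulated genes.
    """

    n_chromosomes: int = 20
    genes_per_chromosome: int = 500
    mean_gene_length: float = 20_000.0
    mean_intergenic_gap: float = 80_000.0
    group_sizes: tuple[int, int] = (4, 5)
    duplicated_interval: tuple[str, int, int] | None = (
        "chr16",
        10_000_000,
        33_000_000,
    )
    dosage_ratio: float = 1.5
    dispersion: float = 0.05
    block_size_genes: int = 10
    block_correlation: float = 0.5
    baseline_expression_log_mean: float = 3.0
    baseline_expression_log_sd: float = 1.2
    sample_noise_log_sd: float = 0.15
    library_size_range: tuple[float, float] = (8e6, 12e6)
    spike_in: int | Sequence[float] | None = None
    global_inflation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("counts must be positive")
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs >= 2 samples")
        if self.dosage_ratio <= 0:
            raise ValueError("dosage_ratio must be positive")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.mean_gene_length <= 0 or self.mean_intergenic_gap < 0:
            raise ValueError("impossible geometry: non-positive length or gap")
        if self.block_size_genes < 1:
            raise ValueError("block_size_genes must be >= 1")
        if self.global_inflation <= 0:
            raise ValueError("global_inflation must be positive")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid library_size_range")
        if self.duplicated_interval is not None:
            chrom, start, end = self.duplicated_interval
            if not 0 <= start < end:
                raise ValueError("duplicated_interval must have start < end")
            idx = _chrom_index(chrom)
            if idx is None or not 1 <= idx <= self.n_chromosomes:
                raise ValueError(
                    f"duplicated_interval chromosome {chrom!r} outside genome"
                )

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(stream + 1)[stream]
        )

    @property
    def n_spike_in(self) -> int:
        if self.spike_in is None:
            return 0
        if isinstance(self.spike_in, int):
            return self.spike_in
        return len(self.spike_in)


def _chrom_index(chrom: str) -> int | None:
    if chrom.startswith("chr"):
        try:
            return int(chrom[3:])
        except ValueError:
            return None
    return None


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside simulated counts."""

    gene_means: pd.DataFrame  # index gene_id, columns mean_A, mean_B
    dosage_ratio: float
    block_boundaries: dict[str, np.ndarray]  # internal boundaries, bases
    block_correlation: float
    spike_in_abundances: pd.Series | None
    global_inflation: float
    duplicated_genes: tuple[str, ...] = ()

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "dosage_ratio": float(self.dosage_ratio),
            "block_correlation": float(self.block_correlation),
            "global_inflation": float(self.global_inflation),
            "block_boundaries": {
                c: [float(p) for p in pos]
                for c, pos in self.block_boundaries.items()
            },
            "duplicated_genes": list(self.duplicated_genes),
            "spike_in_abundances": (
                None
                if self.spike_in_abundances is None
                else {k: float(v) for k, v in self.spike_in_abundances.items()}
            ),
            "gene_means": {
                g: [float(a), float(b)]
                for g, (a, b) in self.gene_means[["mean_A", "mean_B"]]
                .iterrows()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def make_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Non-overlapping, position-sorted synthetic gene annotation.

    Gene lengths are gamma-distributed around ``mean_gene_length`` and
    intergenic gaps exponential around ``mean_intergenic_gap``; genes
    tile each chromosome without overlap by construction. Spike-in
    records (no chromosome, fixed 1 kb length) are appended when
    configured. Deterministic given the config seed.
    """
    rng = config._rng(_STREAM_ANNOTATION)
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        pos = 0.0
        for g in range(config.genes_per_chromosome):
            gap = rng.exponential(config.mean_intergenic_gap)
            length = max(200.0, rng.gamma(4.0, config.mean_gene_length / 4.0))
            start = int(round(pos + gap))
            end = start + int(round(length))
            rows.append(
                {
                    "gene_id": f"{chrom}_g{g + 1:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "is_spike_in": False,
                }
            )
            pos = float(end)
    for k in range(config.n_spike_in):
        rows.append(
            {
                "gene_id": f"spike_{k + 1:03d}",
                "chrom": SPIKE_IN_CHROM,
                "start": 0,
                "end": 1000,
                "strand": ".",
                "is_spike_in": True,
            }
        )
    ann = GeneAnnotation(pd.DataFrame(rows))
    if config.duplicated_interval is not None:
        chrom, start, end = config.duplicated_interval
        extent = ann.data.loc[ann.data["chrom"] == chrom, "end"].max()
        if start >= extent:
            raise ValueError(
                f"duplicated_interval starts beyond {chrom} extent ({extent})"
            )
        ann = ann.mark_excluded_region(chrom, start, end)
    return ann


def _block_ids(annotation: GeneAnnotation, block_size: int) -> pd.Series:
    """Consecutive-gene block labels per chromosome ('chr1:0', ...)."""
    labels = []
    df = annotation.data
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom == SPIKE_IN_CHROM:
            labels.extend([f"{SPIKE_IN_CHROM}:{i}" for i in range(len(sub))])
            continue
        idx = np.arange(len(sub)) // block_size
        labels.extend([f"{chrom}:{i}" for i in idx])
    return pd.Series(labels, index=df["gene_id"])


def _block_boundaries(
    annotation: GeneAnnotation, block_size: int
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    df = annotation.data[~annotation.data["is_spike_in"]]
    for chrom, sub in df.groupby("chrom", sort=False):
        mids = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
        cuts = np.arange(block_size, len(sub), block_size)
        out[chrom] = np.array(
            [(mids[c - 1] + mids[c]) / 2.0 for c in cuts], dtype=float
        )
    return out


def simulate_counts(
    annotation: GeneAnnotation, config: SimulationConfig
) -> tuple[CountMatrix, SimulationTruth]:
    """Negative-binomial counts for two genotype groups.

    mu_gs = libsize_s * basemean_g * effect_gs * exp(noise_gs) with
    effect = dosage_ratio for duplicated genes in group B times
    global_inflation for every non-spike group-B gene. The log-noise of
    gene g in sample s is sample_noise_log_sd * (sqrt(rho) * b_{B(g),s}
    + sqrt(1-rho) * e_{gs}) with the block factor b shared within each
    co-regulation block, inducing correlation ~rho between same-block
    fold changes. Spike-in rows have group-independent, library-size-
    independent means. Counts ~ NB(mu, dispersion) with variance
    mu + dispersion * mu^2 (Poisson at dispersion 0).
    """
    rng = config._rng(_STREAM_COUNTS)
    df = annotation.data
    endo = df[~df["is_spike_in"]]
    if len(endo) != config.n_chromosomes * config.genes_per_chromosome:
        raise ValueError("annotation does not match config geometry")
    n_a, n_b = config.group_sizes
    samples = [f"WT_{i + 1}" for i in range(n_a)] + [
        f"Dp_{i + 1}" for i in range(n_b)
    ]
    groups = ["WT"] * n_a + ["Dp"] * n_b
    design = pd.Series(groups, index=samples, name="group")

    gene_ids = endo["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    basemean = rng.lognormal(
        config.baseline_expression_log_mean,
        config.baseline_expression_log_sd,
        n_genes,
    )

    dup_mask = np.zeros(n_genes, dtype=bool)
    if config.duplicated_interval is not None:
        chrom, start, end = config.duplicated_interval
        mid = (endo["start"] + endo["end"]).to_numpy() / 2.0
        dup_mask = (
            (endo["chrom"].to_numpy() == chrom) & (mid >= start) & (mid < end)
        )

    effect_b = np.where(dup_mask, config.dosage_ratio, 1.0)
    effect_b = effect_b * config.global_inflation

    blocks = _block_ids(annotation, config.block_size_genes)
    block_codes = pd.Categorical(blocks.loc[gene_ids]).codes
    n_blocks = block_codes.max() + 1

    libsizes = rng.uniform(*config.library_size_range, size=len(samples))
    scale = libsizes / basemean.sum()

    rho = config.block_correlation
    sig = config.sample_noise_log_sd
    mu = np.empty((n_genes, len(samples)))
    for j, grp in enumerate(groups):
        b = rng.standard_normal(n_blocks)[block_codes]
        e = rng.standard_normal(n_genes)
        noise = np.exp(sig * (np.sqrt(rho) * b + np.sqrt(1.0 - rho) * e))
        eff = effect_b if grp == "Dp" else 1.0
        mu[:, j] = scale[j] * basemean * eff * noise

    spike_rows = df[df["is_spike_in"]]
    spike_abund = None
    if len(spike_rows):
        if isinstance(config.spike_in, int) or config.spike_in is None:
            mean_lib = float(np.mean(config.library_size_range))
            target = 0.02 * mean_lib / len(spike_rows)
            abund = rng.lognormal(np.log(target), 1.0, len(spike_rows))
        else:
            abund = np.asarray(config.spike_in, dtype=float)
        spike_abund = pd.Series(
            abund, index=spike_rows["gene_id"].to_numpy(), name="abundance"
        )
        # fixed amount per cell: group-independent abundance; sequencing
        # depth multiplies spike-ins and endogenous RNA alike
        depth = libsizes / float(np.mean(config.library_size_range))
        mu = np.vstack([mu, abund[:, None] * depth[None, :]])
        gene_ids = np.concatenate([gene_ids, spike_rows["gene_id"].to_numpy()])

    if config.dispersion > 0:
        size = 1.0 / config.dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                     columns=samples),
        design,
    )
    truth = SimulationTruth(
        gene_means=pd.DataFrame(
            {
                "mean_A": np.concatenate(
                    [basemean, spike_abund.to_numpy()]
                    if spike_abund is not None
                    else [basemean]
                ),
                "mean_B": np.concatenate(
                    [basemean * effect_b, spike_abund.to_numpy()]
                    if spike_abund is not None
                    else [basemean * effect_b]
                ),
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        dosage_ratio=config.dosage_ratio,
        block_boundaries=_block_boundaries(annotation, config.block_size_genes),
        block_correlation=rho,
        spike_in_abundances=spike_abund,
        global_inflation=config.global_inflation,
        duplicated_genes=tuple(endo["gene_id"].to_numpy()[dup_mask]),
    )
    return cm, truth


def simulate_signed_profile(
    n_genes: int, rho: float, sigma: float, seed: int = 0,
    chrom: str = "chr1", spacing: float = 100_000.0,
) -> FoldChangeProfile:
    """Directly generated AR(1) fold-change profile for unit tests.

    h_i = rho * h_{i-1} + sqrt(1 - rho^2) * eps_i with eps ~ N(0,
    sigma^2), so the stationary SD is sigma at every position. rho = 0
    gives i.i.d. values whose expected flip count is (N - 1) / 2.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, n_genes)
    h = np.empty(n_genes)
    h[0] = eps[0]
    c = np.sqrt(1.0 - rho * rho)
    for i in range(1, n_genes):
        h[i] = rho * h[i - 1] + c * eps[i]
    starts = np.arange(n_genes) * spacing
    df = pd.DataFrame(
        {
            "gene_id": [f"{chrom}_g{i + 1:05d}" for i in range(n_genes)],
            "chrom": chrom,
            "start": starts,
            "end": starts + spacing / 2.0,
            "midpoint": starts + spacing / 4.0,
            "h": h,
            "mean_rpkm": 10.0,
            "excluded": False,
        }
    )
    return FoldChangeProfile(df)


def make_feature_tracks(
    annotation: GeneAnnotation,
    truth: SimulationTruth,
    jitter: float = 0.0,
    seed: int = 0,
) -> dict[str, BoundaryTrack]:
    """Synthetic chromatin-feature tracks aligned to the truth blocks.

    TAD boundaries are the true co-regulation block boundaries displaced
    by uniform +/- jitter; CTCF sites sit at TAD boundaries plus an
    equal number of uniform background sites; LADs merge pairs of
    adjacent blocks (so LAD boundaries are a subset, count <= TAD
    count); replication domains are an independent random segmentation.
    All positions are clipped to the chromosome extent.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng([seed, _STREAM_TRACKS])
    endo = annotation.data[~annotation.data["is_spike_in"]]
    extents = {
        chrom: (float(sub["start"].min()), float(sub["end"].max()))
        for chrom, sub in endo.groupby("chrom", sort=False)
    }
    tad_rows, ctcf_rows, lad_rows, rd_rows = [], [], [], []
    for chrom in sorted(truth.block_boundaries):
        bnd = truth.block_boundaries[chrom]
        lo, hi = extents[chrom]
        if jitter > 0:
            tad = np.clip(bnd + rng.uniform(-jitter, jitter, len(bnd)), lo, hi)
        else:
            tad = bnd.copy()
        tad_rows.extend({"chrom": chrom, "pos": p} for p in tad)
        bg = rng.uniform(lo, hi, len(tad))
        ctcf_rows.extend({"chrom": chrom, "pos": p} for p in tad)
        ctcf_rows.extend({"chrom": chrom, "pos": p} for p in np.sort(bg))
        # LADs: unions of adjacent block pairs -> every second boundary
        lad_rows.extend({"chrom": chrom, "pos": p} for p in bnd[1::2])
        n_rd = max(1, len(bnd) // 3)
        rd = np.sort(rng.uniform(lo, hi, n_rd))
        rd_rows.extend({"chrom": chrom, "pos": p} for p in rd)
    return {
        "TAD": BoundaryTrack("TAD", pd.DataFrame(tad_rows)),
        "CTCF": BoundaryTrack("CTCF", pd.DataFrame(ctcf_rows)),
        "LAD": BoundaryTrack("LAD", pd.DataFrame(lad_rows)),
        "RD": BoundaryTrack("RD", pd.DataFrame(rd_rows)),
    }


def write_dataset(
    outdir: str | Path,
    config: SimulationConfig,
    jitter: float = 0.0,
) -> None:
    """Generate and write a full synthetic dataset to ``outdir``.

    Writes counts.tsv, design.tsv, annotation.bed (BED6), truth.yaml,
    and one BED3 per feature track.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = make_annotation(config)
    counts, truth = simulate_counts(ann, config)
    tracks = make_feature_tracks(ann, truth, jitter=jitter, seed=config.seed)
    ann.to_bed(outdir / "annotation.bed")
    counts.to_tsv(outdir / "counts.tsv", outdir / "design.tsv")
    truth.to_yaml(outdir / "truth.yaml")
    for name, track in tracks.items():
        track.to_bed(outdir / f"{name.lower()}_boundaries.bed")
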