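"""Normalization, expression filtering, and fold-change profiles.

This module bridges raw gene-level counts to the position-ordered vector
of signed log2 fold changes ``h`` that the clustering statistics consume:
RPKM computation, a density-fit expression cutoff, median-of-ratios size
factors (with an optional spike-in reference for absolute normalization),
and construction of per-chromosome fold-change profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CountMatrix, GeneAnnotation

__all__ = [
    "ExpressionCutoff",
    "FoldChangeProfile",
    "compute_rpkm",
    "fit_expression_cutoff",
    "size_factors",
    "fold_change_profile",
    "compare_normalizations",
    "stratify_fold_changes",
    "profile_correlation",
    "RPKM_STRATA",
]

# Expression strata by mean RPKM, half-open [low, high): a gene at exactly
# 10 falls in "medium", at exactly 100 in "high".
RPKM_STRATA = (
    ("low", 0.1, 10.0),
    ("medium", 10.0, 100.0),
    ("high", 100.0, np.inf),
)


def compute_rpkm(counts: CountMatrix, annotation: GeneAnnotation) -> pd.DataFrame:
    """Reads per kilobase of gene model per million mapped reads.

    The per-sample total is taken over non-spike-in genes only, so that
    spike-in abundance does not dilute the mapped-read denominator.
    """
    lengths = annotation.lengths().reindex(counts.gene_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"gene {missing!r} absent from annotation")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    spike = (
        annotation.data.set_index("gene_id")["is_spike_in"]
        .reindex(counts.gene_ids)
        .fillna(False)
    )
    totals = counts.counts.loc[~spike.to_numpy()].sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    denom = np.outer(lengths.to_numpy() / 1e3, totals.to_numpy() / 1e6)
    return pd.DataFrame(
        counts.counts.to_numpy() / denom,
        index=counts.gene_ids,
        columns=counts.samples,
    )


@dataclass(frozen=True)
class ExpressionCutoff:
    """Gaussian fit to the expressed mode of the log2 mean-RPKM density.

    ``threshold = mu - 3 * sigma`` on the log2[RPKM] scale; genes above
    the threshold are considered expressed.
    """

    mu: float
    sigma: float

    @property
    def threshold(self) -> float:
        return self.mu - 3.0 * self.sigma

    def is_expressed(self, mean_rpkm: np.ndarray | pd.Series) -> np.ndarray:
        vals = np.asarray(mean_rpkm, dtype=float)
        with np.errstate(divide="ignore"):
            log2 = np.log2(vals)
        return log2 > self.threshold


def fit_expression_cutoff(
    mean_rpkm: np.ndarray | pd.Series, n_grid: int = 512
) -> ExpressionCutoff:
    """Fit a normal to the main mode of the log2 mean-RPKM density.

    A Gaussian KDE of log2(mean RPKM) over genes with positive mean is
    evaluated on a grid; the mode locates mu-hat, and sigma-hat is the
    upper half-width where the density falls to exp(-1/2) of the peak
    (mirrored about the mode). Silent-gene modes at lower expression are
    thereby ignored.
    """
    vals = np.asarray(mean_rpkm, dtype=float)
    vals = vals[vals > 0]
    if len(vals) < 100:
        raise ValueError("need >= 100 genes with positive mean RPKM")
    log2 = np.log2(vals)
    if np.ptp(log2) == 0:
        raise ValueError("all mean RPKM equal; cutoff undefined, set manually")
    try:
        # 1.5x Scott's factor: oversmooth to suppress KDE wiggle around
        # the mode; the bandwidth is deconvolved from sigma-hat below
        kde = sps.gaussian_kde(log2, bw_method=1.5 * len(log2) ** (-0.2))
    except np.linalg.LinAlgError as exc:  # degenerate spread
        raise ValueError(
            "degenerate log2 RPKM distribution; set threshold manually"
        ) from exc
    grid = np.linspace(log2.min(), log2.max(), n_grid)
    dens = kde(grid)
    imode = int(np.argmax(dens))
    if imode in (0, n_grid - 1):
        raise ValueError(
            "no interior density mode found; set threshold manually"
        )
    peak = dens[imode]
    below = np.nonzero(dens[imode:] < peak * np.exp(-0.5))[0]
    if len(below) == 0:
        raise ValueError(
            "density never falls to exp(-1/2) of the peak above the mode; "
            "set threshold manually"
        )
    width = grid[imode + below[0]] - grid[imode]
    # the KDE of N(mu, s^2) is N(mu, s^2 + bw^2): remove the bandwidth
    bw = kde.factor * log2.std(ddof=1)
    sigma = float(np.sqrt(max(width**2 - bw**2, (width / 4) ** 2)))
    return ExpressionCutoff(mu=float(grid[imode]), sigma=sigma)


def size_factors(
    counts: CountMatrix | pd.DataFrame,
    reference_genes: set[str] | list[str] | None = None,
) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    factor_s = median over reference genes g of count_gs / geomean_g,
    where geomean_g is the geometric mean of gene g across samples. The
    default reference is all genes with all-positive counts; passing
    spike-in ids yields absolute (per-cell) normalization. Factors are
    rescaled to geometric mean 1.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if reference_genes is not None:
        ref = [g for g in reference_genes if g in mat.index]
        if not ref:
            raise ValueError("reference gene set is empty or absent from counts")
        mat = mat.loc[ref]
    arr = mat.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with all-positive counts for normalization")
    arr = arr[allpos]
    log_geomean = np.log(arr).mean(axis=1)
    ratios = np.log(arr) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="size_factor")


PROFILE_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "midpoint",
    "h",
    "mean_rpkm",
    "excluded",
]


@dataclass
class FoldChangeProfile:
    """Position-ordered signed log2 fold changes, per chromosome.

    One row per expressed gene: ``gene_id, chrom, start, end, midpoint,
    h, mean_rpkm, excluded``. Excluded genes (e.g. within a duplicated
    interval) are retained for plotting but omitted from statistic
    inputs.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True).copy()
        missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"profile missing columns: {missing}")
        if not np.isfinite(df["h"].to_numpy(dtype=float)).all():
            raise ValueError("fold changes must be finite")
        df = df.sort_values(
            ["chrom", "start", "end", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            mids = sub["midpoint"].to_numpy()
            if np.any(np.diff(mids) < 0):
                raise ValueError(f"profile not position-ordered on {chrom}")
        self.data = df[PROFILE_COLUMNS]

    def __len__(self) -> int:
        return len(self.data)

    def chromosomes(self) -> list[str]:
        return sorted(self.data["chrom"].unique())

    def chromosome(
        self, chrom: str, include_excluded: bool = False
    ) -> pd.DataFrame:
        sub = self.data[self.data["chrom"] == chrom]
        if not include_excluded:
            sub = sub[~sub["excluded"]]
        return sub.reset_index(drop=True)

    def h_values(self, chrom: str, include_excluded: bool = False) -> np.ndarray:
        return self.chromosome(chrom, include_excluded)["h"].to_numpy(dtype=float)

    def negated(self) -> "FoldChangeProfile":
        df = self.data.copy()
        df["h"] = -df["h"]
        return FoldChangeProfile(df)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FoldChangeProfile":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df)


def fold_change_profile(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    groups: tuple[str, str],
    cutoff: ExpressionCutoff | float | None = None,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
    min_genes: int = 3,
) -> FoldChangeProfile:
    """Per-chromosome profile of h = log2 fold change (group B vs A).

    h_g = log2[(mean normalized count in B + c) / (mean in A + c)] with
    pseudocount ``c`` in normalized-count units. Genes below the
    expression cutoff and spike-ins are dropped; genes flagged excluded
    in the annotation are retained but marked. Chromosomes left with
    fewer than ``min_genes`` expressed genes are dropped with a warning
    (recorded on ``profile.skipped_chromosomes``).

    Parameters
    ----------
    groups : (name_A, name_B)
        Design group labels; fold changes are B over A.
    cutoff : ExpressionCutoff, float (log2 RPKM threshold), or None
        None keeps every gene with positive mean RPKM.
    """
    name_a, name_b = groups
    samples_a = counts.group_samples(name_a)
    samples_b = counts.group_samples(name_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.counts / factors.reindex(counts.samples)
    rpkm = compute_rpkm(counts, annotation)
    mean_rpkm = rpkm.mean(axis=1)

    ann = annotation.data.set_index("gene_id").reindex(counts.gene_ids)
    if ann["chrom"].isna().any():
        bad = ann.index[ann["chrom"].isna()][0]
        raise ValueError(f"gene {bad!r} absent from annotation")

    if cutoff is None:
        expressed = mean_rpkm > 0
    else:
        threshold = cutoff if isinstance(cutoff, float) else cutoff.threshold
        with np.errstate(divide="ignore"):
            expressed = np.log2(mean_rpkm.to_numpy(dtype=float)) > threshold
        expressed = pd.Series(expressed, index=mean_rpkm.index)

    keep = expressed & ~ann["is_spike_in"].astype(bool)
    mean_a = norm.loc[keep, samples_a].mean(axis=1)
    mean_b = norm.loc[keep, samples_b].mean(axis=1)
    h = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    sub = ann.loc[keep]
    df = pd.DataFrame(
        {
            "gene_id": sub.index,
            "chrom": sub["chrom"].to_numpy(),
            "start": sub["start"].to_numpy(),
            "end": sub["end"].to_numpy(),
            "midpoint": (sub["start"] + sub["end"]).to_numpy() / 2.0,
            "h": h.to_numpy(),
            "mean_rpkm": mean_rpkm.loc[keep].to_numpy(),
            "excluded": sub["is_excluded"].to_numpy(dtype=bool),
        }
    )
    skipped = []
    for chrom, grp in df.groupby("chrom"):
        if (~grp["excluded"]).sum() < min_genes:
            skipped.append(str(chrom))
    if skipped:
        warnings.warn(
            f"chromosomes with < {min_genes} expressed genes dropped: {skipped}"
        )
        df = df[~df["chrom"].isin(skipped)]
    profile = FoldChangeProfile(df)
    profile.skipped_chromosomes = skipped  # type: ignore[attr-defined]
    return profile


def _stratum_labels(mean_rpkm: pd.Series) -> pd.Series:
    labels = pd.Series(pd.NA, index=mean_rpkm.index, dtype="object")
    for name, lo, hi in RPKM_STRATA:
        labels[(mean_rpkm >= lo) & (mean_rpkm < hi)] = name
    return labels


def compare_normalizations(
    counts: CountMatrix,
    spikein_ids: list[str] | set[str],
    groups: tuple[str, str],
    annotation: GeneAnnotation | None = None,
    pseudocount: float = 0.5,
) -> dict:
    """Global shift between absolute (spike-in) and relative normalization.

    Returns the relative excess of the mean linear fold change under
    spike-in (absolute) size factors over the mean under all-gene
    (relative) factors, i.e. mean(FC_abs)/mean(FC_rel) - 1. A genuinely
    inflated transcriptome in group B appears as a positive shift:
    relative normalization absorbs a global increase that absolute
    normalization preserves. Per-expression-stratum shifts are also
    returned to detect skew toward low- or high-expressed genes.
    """
    spikein_ids = [g for g in spikein_ids if g in counts.gene_ids]
    if not spikein_ids:
        raise ValueError("no spike-in ids found in counts")
    spike_counts = counts.counts.loc[spikein_ids]
    if (spike_counts.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero spike-in counts")
    name_a, name_b = groups
    samples_a = counts.group_samples(name_a)
    samples_b = counts.group_samples(name_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("spike-ins must be present in >= 2 samples per group")

    endo = counts.counts.drop(index=spikein_ids)
    factors_rel = size_factors(endo)
    factors_abs = size_factors(counts.counts.loc[spikein_ids])

    def _linear_fc(factors: pd.Series) -> pd.Series:
        norm = endo / factors.reindex(endo.columns)
        ma = norm[samples_a].mean(axis=1)
        mb = norm[samples_b].mean(axis=1)
        return (mb + pseudocount) / (ma + pseudocount)

    fc_rel = _linear_fc(factors_rel)
    fc_abs = _linear_fc(factors_abs)
    shift = float(fc_abs.mean() / fc_rel.mean() - 1.0)

    if annotation is not None:
        rpkm = compute_rpkm(counts, annotation)
        strata = _stratum_labels(rpkm.loc[endo.index].mean(axis=1))
    else:
        # no lengths available: tercile strata on mean relative-normalized
        # counts as an expression-level proxy
        level = (endo / factors_rel).mean(axis=1)
        q = level.rank(pct=True)
        strata = pd.Series(
            np.where(q < 1 / 3, "low", np.where(q < 2 / 3, "medium", "high")),
            index=endo.index,
        )
    per_stratum = {}
    for name in ("low", "medium", "high"):
        mask = (strata == name).to_numpy()
        if mask.sum() == 0:
            continue
        per_stratum[name] = float(
            fc_abs[mask].mean() / fc_rel[mask].mean() - 1.0
        )
    return {
        "shift": shift,
        "per_stratum": per_stratum,
        "factors_relative": factors_rel,
        "factors_absolute": factors_abs,
    }


def stratify_fold_changes(
    profile: FoldChangeProfile, control_profile: FoldChangeProfile
) -> pd.DataFrame:
    """Compare fold-change distributions by expression stratum.

    Genes are binned by mean RPKM into low [0.1, 10), medium [10, 100)
    and high [100, inf) strata; within each stratum the test profile's h
    values are compared to the control profile's with a two-sided
    Mann-Whitney U test (normal approximation, tie-corrected). Empty
    strata are reported absent.
    """
    rows = []
    for name, lo, hi in RPKM_STRATA:
        t = profile.data
        c = control_profile.data
        ht = t.loc[(t["mean_rpkm"] >= lo) & (t["mean_rpkm"] < hi), "h"]
        hc = c.loc[(c["mean_rpkm"] >= lo) & (c["mean_rpkm"] < hi), "h"]
        if len(ht) == 0 or len(hc) == 0:
            continue
        res = sps.mannwhitneyu(ht, hc, alternative="two-sided", method="asymptotic")
        rows.append(
            {
                "stratum": name,
                "n_test": len(ht),
                "n_control": len(hc),
                "U": float(res.statistic),
                "p_value": float(res.pvalue),
                "median_shift": float(ht.median() - hc.median()),
            }
        )
    return pd.DataFrame(rows)


def profile_correlation(
    profile_a: FoldChangeProfile,
    profile_b: FoldChangeProfile,
    id_map: dict[str, str] | None = None,
) -> tuple[float, int]:
    """Pearson correlation of h over shared non-excluded genes.

    ``id_map`` maps profile-A gene ids to profile-B ids (e.g. mouse
    orthologues); identity when None. Returns (r, n_shared); r is NaN if
    either vector has zero variance.
    """
    a = profile_a.data[~profile_a.data["excluded"]].set_index("gene_id")["h"]
    b = profile_b.data[~profile_b.data["excluded"]].set_index("gene_id")["h"]
    if id_map is not None:
        a = a[a.index.isin(id_map)]
        a.index = [id_map[g] for g in a.index]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes after exclusions")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), len(shared)
    r = float(np.corrcoef(x, y)[0, 1])
    return r, len(shared)
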