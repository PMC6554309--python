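"""Display-layer smoothing and report rendering.

The Loess curve is purely a visual aid for fold-change plots along a
chromosome — regions where the curve is positive/negative are coloured
as up-/down-regulated — and is never used for inference.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .domains import DensityCurve, GEDDDomain, domains_to_frame
from .expression import FoldChangeProfile
from .stats import GenomeScanResult, NullDistribution

__all__ = ["loess_curve", "render_report"]


def loess_curve(
    positions: np.ndarray, h: np.ndarray, span: float = 0.75
) -> np.ndarray:
    """Local linear (tricube-weighted) smooth of h along positions.

    ``span`` is the fraction of neighbours in each local fit. Returns
    the smoothed values at the input positions (input order preserved).
    """
    positions = np.asarray(positions, dtype=float)
    h = np.asarray(h, dtype=float)
    if len(positions) != len(h):
        raise ValueError("positions and h differ in length")
    if len(h) < 10:
        raise ValueError("need >= 10 points for a Loess curve")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if span * len(h) < 3:
        raise ValueError("span too small for local linear fits")
    return lowess(
        h, positions, frac=span, it=0, return_sorted=False
    )


def _plot_profile(
    profile: FoldChangeProfile, chrom: str, span: float, path: Path
) -> None:
    sub = profile.chromosome(chrom, include_excluded=True)
    pos = sub["midpoint"].to_numpy() / 1e6
    h = sub["h"].to_numpy()
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(pos, h, s=6, color="grey", alpha=0.6)
    if len(h) >= 10:
        curve = loess_curve(sub["midpoint"].to_numpy(), h, span=span)
        up = curve >= 0
        ax.plot(pos[up], curve[up], ".", color="red", ms=2)
        ax.plot(pos[~up], curve[~up], ".", color="green", ms=2)
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel(f"{chrom} position (Mb)")
    ax.set_ylabel("log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_null_histogram(
    null: NullDistribution, observed: float, path: Path
) -> None:
    """Permutation-null histogram with 2-SD and 3-SD guide lines."""
    fig, ax = plt.subplots(figsize=(4, 3))
    if null.samples is not None:
        ax.hist(null.samples, bins=50, color="lightgrey")
    for k, color in ((2, "pink"), (3, "purple")):
        for sign in (-1, 1):
            ax.axvline(null.mean + sign * k * null.sd, color=color, lw=1)
    ax.axvline(observed, color="black", ls="--", lw=1.2)
    ax.set_xlabel(null.metric)
    ax.set_ylabel("permutations")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_report(
    outdir: str | Path,
    scan: GenomeScanResult | None = None,
    switch_summary: pd.DataFrame | None = None,
    domains: list[GEDDDomain] | None = None,
    densities: dict[str, DensityCurve] | None = None,
    profile: FoldChangeProfile | None = None,
    comparison_name: str = "caseB_vs_groupA",
    span: float = 0.75,
) -> dict[str, Path]:
    """Write figures and machine-readable summaries for available stages.

    File names are deterministic. ``summary.tsv`` has one row per
    comparison with the two significant-chromosome counts, taken
    directly from the per-chromosome flags (never recomputed). Missing
    stages are listed in ``missing.txt`` instead of failing.
    """
    if all(
        x is None for x in (scan, switch_summary, domains, densities, profile)
    ):
        raise ValueError("nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    missing: list[str] = []

    if scan is not None:
        table_path = outdir / "scan_per_chromosome.tsv"
        scan.table.to_csv(table_path, sep="\t", index=False)
        written["scan_table"] = table_path
        summary = pd.DataFrame(
            [
                {
                    "comparison": comparison_name,
                    "flips_significant": scan.n_flips_significant,
                    "energy_significant": scan.n_energy_significant,
                }
            ]
        )
        summary_path = outdir / "summary.tsv"
        summary.to_csv(summary_path, sep="\t", index=False)
        written["summary"] = summary_path
        first = scan.results[0]
        if first.flips_null.samples is not None:
            _plot_null_histogram(
                first.flips_null,
                first.flips,
                outdir / f"null_flips_{first.chromosome}.png",
            )
    else:
        missing.append("scan")

    if profile is not None:
        for chrom in profile.chromosomes()[:4]:
            p = outdir / f"profile_{chrom}.png"
            _plot_profile(profile, chrom, span, p)
            written[f"profile_{chrom}"] = p
    else:
        missing.append("profile")

    if switch_summary is not None:
        p = outdir / "switch_summary.tsv"
        switch_summary.to_csv(p, sep="\t", index=False)
        written["switch_summary"] = p
    else:
        missing.append("switch")

    if domains is not None:
        p = outdir / "domains.tsv"
        domains_to_frame(domains).to_csv(p, sep="\t", index=False)
        written["domains"] = p
    else:
        missing.append("domains")

    if densities is not None:
        for name, curve in sorted(densities.items()):
            p = outdir / f"density_{name}.tsv"
            curve.to_tsv(p)
            written[f"density_{name}"] = p
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for name, curve in sorted(densities.items()):
            ax.plot(curve.grid / 1e6, curve.density * 1e6, label=name)
        ax.set_xlabel("distance to boundary (Mb)")
        ax.set_ylabel("density (per Mb)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "boundary_density.png", dpi=100)
        plt.close(fig)
        written["density_figure"] = outdir / "boundary_density.png"
    else:
        missing.append("densities")

    if missing:
        gaps = outdir / "missing.txt"
        gaps.write_text("\n".join(missing) + "\n")
        written["missing"] = gaps
    return written
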