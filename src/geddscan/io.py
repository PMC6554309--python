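"""Containers and readers/writers for gene-level expression data.

Coordinates are 0-based, half-open internally (BED convention). GTF input
(1-based, closed) is converted on read. Spike-in transcripts carry no
chromosome and are stored with the placeholder chromosome ``"."``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SPIKE_IN_CHROM",
    "GeneAnnotation",
    "CountMatrix",
    "read_annotation",
    "read_counts",
]

SPIKE_IN_CHROM = "."

ANNOTATION_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "length",
    "is_spike_in",
    "is_excluded",
]

_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


@dataclass
class GeneAnnotation:
    """Gene coordinates defining chromosomal order.

    ``data`` holds one row per gene with columns ``gene_id, chrom, start,
    end, strand, length, is_spike_in, is_excluded``. Within a chromosome
    genes sort by ``(start, end, gene_id)``; strand is ignored for
    ordering.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True).copy()
        for col in ("is_spike_in", "is_excluded"):
            if col not in df.columns:
                df[col] = False
        if "length" not in df.columns:
            df["length"] = df["end"] - df["start"]
        if "strand" not in df.columns:
            df["strand"] = "."
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene id: {dup.iloc[0]!r}")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
            raise ValueError(f"gene {bad!r} has start >= end")
        if not df["strand"].isin(["+", "-", "."]).all():
            raise ValueError("strand must be one of '+', '-', '.'")
        df = df.sort_values(
            ["chrom", "start", "end", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        self.data = df[ANNOTATION_COLUMNS]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.data["gene_id"])

    def chromosomes(self) -> list[str]:
        """Chromosome names (spike-in placeholder excluded), sorted."""
        chroms = self.data.loc[~self.data["is_spike_in"], "chrom"].unique()
        return sorted(chroms)

    def midpoints(self) -> pd.Series:
        mid = (self.data["start"] + self.data["end"]) / 2.0
        mid.index = self.data["gene_id"]
        return mid

    def lengths(self) -> pd.Series:
        s = self.data.set_index("gene_id")["length"].astype(float)
        return s

    def mark_excluded_region(
        self, chrom: str, start: int, end: int
    ) -> "GeneAnnotation":
        """Return a copy with genes overlapping ``chrom:start-end`` flagged
        as excluded (e.g. a duplicated trisomic interval)."""
        df = self.data.copy()
        hit = (
            (df["chrom"] == chrom) & (df["start"] < end) & (df["end"] > start)
        )
        df.loc[hit, "is_excluded"] = True
        return GeneAnnotation(df)

    def to_bed(self, path: str | Path) -> None:
        """Write BED6; spike-ins are written with chromosome '.'."""
        df = self.data
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"].astype(int),
                "end": df["end"].astype(int),
                "name": df["gene_id"],
                "score": 0,
                "strand": df["strand"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def _read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return pd.DataFrame(
        {
            "gene_id": df["name"],
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "strand": df["strand"].fillna("."),
            "is_spike_in": df["chrom"] == SPIKE_IN_CHROM,
        }
    )


def _read_gtf(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            m = _GTF_GENE_ID.search(f[8])
            if m is None:
                raise ValueError(f"GTF gene record without gene_id: {line!r}")
            # GTF is 1-based closed; internal is 0-based half-open
            rows.append(
                {
                    "gene_id": m.group(1),
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6] if f[6] in "+-" else ".",
                    "is_spike_in": f[0] == SPIKE_IN_CHROM,
                }
            )
    return pd.DataFrame(rows)


def read_annotation(path: str | Path, format: str = "BED") -> GeneAnnotation:
    """Read gene annotation from BED6 or GTF.

    GTF ``gene`` features only; coordinates converted to 0-based
    half-open.
    """
    fmt = format.upper()
    if fmt == "BED":
        df = _read_bed(path)
    elif fmt == "GTF":
        df = _read_gtf(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GeneAnnotation(df)


@dataclass
class CountMatrix:
    """Gene-level counts (genes x samples) with a sample->group design.

    ``counts`` is indexed by gene id; ``design`` maps every sample
    (column) to its group label.
    """

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        neg = np.argwhere(arr < 0)
        if len(neg):
            r, c = neg[0]
            raise ValueError(
                f"negative count at gene {counts.index[r]!r}, "
                f"sample {counts.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        design = self.design
        missing = [s for s in counts.columns if s not in design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        self.design = design.reindex(counts.columns)

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def group_samples(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.design[list(samples)])

    def with_design(self, design: pd.Series) -> "CountMatrix":
        return CountMatrix(self.counts, design)

    def to_tsv(self, counts_path: str | Path, design_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.design.rename("group").to_csv(
            design_path, sep="\t", index_label="sample"
        )


def read_counts(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column gene id) and a design TSV
    (columns ``sample``, ``group``)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design_df = pd.read_csv(design_path, sep="\t")
    if not {"sample", "group"} <= set(design_df.columns):
        raise ValueError("design file must have columns 'sample' and 'group'")
    design = design_df.set_index("sample")["group"]
    return CountMatrix(counts, design)
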