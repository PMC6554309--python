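"""Balanced genotype relabeling ("no-genotype-difference") controls.

Splitting samples into two sides that each contain equal numbers of both
true genotypes removes the genotype effect from the comparison; any
clustering of fold changes that survives such a relabeling reflects
sample-to-sample variation, not genotype. With four samples per genotype
and two of each per side there are C(4,2)^2 / 2 = 18 distinct
relabelings (a relabeling and its side-swap are the same comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import pandas as pd

from .expression import ExpressionCutoff, fold_change_profile
from .io import CountMatrix, GeneAnnotation
from .stats import GenomeScanResult, scan_genome

__all__ = [
    "Relabeling",
    "enumerate_balanced_relabelings",
    "run_relabeling_scan",
]


@dataclass(frozen=True)
class Relabeling:
    """One balanced split: each side holds per_side samples per genotype.

    Stored in canonical form: each side sorted, and the lexicographically
    smaller side first, so a relabeling equals its side-swap.
    """

    side_a: tuple[str, ...]
    side_b: tuple[str, ...]

    @classmethod
    def canonical(cls, side_a, side_b) -> "Relabeling":
        a = tuple(sorted(side_a))
        b = tuple(sorted(side_b))
        if set(a) & set(b):
            raise ValueError("sides must be disjoint")
        if b < a:
            a, b = b, a
        return cls(a, b)

    def swapped(self) -> "Relabeling":
        """The side-swapped comparison (canonically identical)."""
        return Relabeling.canonical(self.side_b, self.side_a)


def _as_ids(group, prefix: str) -> list[str]:
    if isinstance(group, int):
        return [f"{prefix}{i + 1}" for i in range(group)]
    ids = list(group)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids within a genotype")
    return ids


def enumerate_balanced_relabelings(
    genotype1, genotype2, per_side: int = 2
) -> list[Relabeling]:
    """All distinct balanced relabelings of two genotype groups.

    Each genotype must contribute exactly ``2 * per_side`` samples (pass
    an explicit subset if more are available); each side of every
    relabeling receives ``per_side`` samples of each genotype. The count
    is C(2k, k)^2 / 2 with k = per_side: 2 for (2, 2, 1), 18 for
    (4, 4, 2), 200 for (6, 6, 3).

    Parameters
    ----------
    genotype1, genotype2 : int or sequence of sample ids
        Integer n generates placeholder ids; a sequence uses real ids.
    """
    if per_side < 1:
        raise ValueError("per_side must be >= 1")
    g1 = _as_ids(genotype1, "g1_")
    g2 = _as_ids(genotype2, "g2_")
    if set(g1) & set(g2):
        raise ValueError("genotype groups share sample ids")
    for name, g in (("genotype1", g1), ("genotype2", g2)):
        if len(g) != 2 * per_side:
            raise ValueError(
                f"{name} has {len(g)} samples but exactly {2 * per_side} are "
                "used; choose the subset explicitly"
            )
    seen: set[Relabeling] = set()
    out: list[Relabeling] = []
    for pick1 in combinations(g1, per_side):
        rest1 = [s for s in g1 if s not in pick1]
        for pick2 in combinations(g2, per_side):
            rest2 = [s for s in g2 if s not in pick2]
            rel = Relabeling.canonical(pick1 + pick2, tuple(rest1 + rest2))
            if rel not in seen:
                seen.add(rel)
                out.append(rel)
    expected = comb(len(g1), per_side) * comb(len(g2), per_side) // 2
    assert len(out) == expected, (len(out), expected)
    return sorted(out, key=lambda r: (r.side_a, r.side_b))


def run_relabeling_scan(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    relabelings: list[Relabeling],
    cutoff: ExpressionCutoff | float | None = None,
    pseudocount: float = 0.5,
    n_permutations: int = 100_000,
    sd_threshold: float = 2.0,
    seed: int = 0,
) -> tuple[list[tuple[Relabeling, GenomeScanResult]], pd.DataFrame]:
    """Genome scan for every balanced relabeling.

    For each relabeling a fold-change profile (side B vs side A) is
    built from the same counts and the clustering scan is run. Returns
    the per-relabeling scan results and a summary table (one row per
    relabeling with its significant-chromosome counts). All relabelings
    share the same scan seed so that differences between rows reflect
    the relabeling alone.
    """
    results = []
    rows = []
    for idx, rel in enumerate(relabelings):
        samples = list(rel.side_a) + list(rel.side_b)
        missing = [s for s in samples if s not in counts.samples]
        if missing:
            raise ValueError(f"samples absent from counts: {missing}")
        design = pd.Series(
            ["sideA"] * len(rel.side_a) + ["sideB"] * len(rel.side_b),
            index=samples,
            name="group",
        )
        sub = counts.subset_samples(samples).with_design(design)
        profile = fold_change_profile(
            sub,
            annotation,
            groups=("sideA", "sideB"),
            cutoff=cutoff,
            pseudocount=pseudocount,
        )
        scan = scan_genome(
            profile,
            n_permutations=n_permutations,
            sd_threshold=sd_threshold,
            seed=seed,
        )
        results.append((rel, scan))
        rows.append(
            {
                "relabeling": idx,
                "side_a": "+".join(rel.side_a),
                "side_b": "+".join(rel.side_b),
                "n_chromosomes": len(scan.results),
                "flips_significant": scan.n_flips_significant,
                "energy_significant": scan.n_energy_significant,
            }
        )
    return results, pd.DataFrame(rows)
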