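import numpy as np
import pandas as pd
import pytest

import geddscan as g


@pytest.fixture(scope="session")
def small_config():
    """A compact two-genotype study: 4 chromosomes, a duplicated
    interval on chr2 at 1.5x, no block co-regulation."""
    return g.SimulationConfig(
        n_chromosomes=4,
        genes_per_chromosome=120,
        group_sizes=(4, 4),
        duplicated_interval=("chr2", 1_000_000, 7_000_000),
        block_correlation=0.0,
        sample_noise_log_sd=0.1,
        spike_in=24,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ann = g.make_annotation(small_config)
    counts, truth = g.simulate_counts(ann, small_config)
    return ann, counts, truth


@pytest.fixture(scope="session")
def small_profile(small_dataset):
    ann, counts, _ = small_dataset
    return g.fold_change_profile(counts, ann, groups=("WT", "Dp"))


@pytest.fixture()
def tiny_annotation():
    """Hand-written three-gene annotation on one chromosome."""
    df = pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "chrom": ["chr1"] * 3,
            "start": [100, 2000, 5000],
            "end": [1100, 3000, 7000],
            "strand": ["+", "-", "+"],
        }
    )
    return g.GeneAnnotation(df)


def make_profile(h, midpoints=None, chrom="chr1", excluded=None, mean_rpkm=10.0):
    """Build a FoldChangeProfile directly from an h vector."""
    h = np.asarray(h, dtype=float)
    n = len(h)
    if midpoints is None:
        midpoints = 1e5 * np.arange(n) + 5e4
    midpoints = np.asarray(midpoints, dtype=float)
    starts = midpoints - 1e3
    df = pd.DataFrame(
        {
            "gene_id": [f"{chrom}_g{i}" for i in range(n)],
            "chrom": chrom,
            "start": starts,
            "end": midpoints + 1e3,
            "midpoint": midpoints,
            "h": h,
            "mean_rpkm": mean_rpkm,
            "excluded": excluded if excluded is not None else False,
        }
    )
    return g.FoldChangeProfile(df)
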