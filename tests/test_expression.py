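import numpy as np
import pandas as pd
import pytest

import geddscan as g
from conftest import make_profile


def _two_gene_counts():
    counts = pd.DataFrame(
        {"s1": [1000, 999_000], "s2": [1000, 999_000]},
        index=["gA", "gB"],
    )
    design = pd.Series({"s1": "WT", "s2": "WT"})
    ann = g.GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["chr1", "chr1"],
                "start": [0, 10_000],
                "end": [1000, 12_000],
            }
        )
    )
    return g.CountMatrix(counts, design), ann


class TestRpkm:
    def test_unit_case(self):
        # count 1000, length 1 kb, library 1e6 -> RPKM 1000
        counts, ann = _two_gene_counts()
        rpkm = g.compute_rpkm(counts, ann)
        assert rpkm.loc["gA", "s1"] == pytest.approx(1000.0)

    def test_doubling_length_halves_rpkm(self):
        counts, ann = _two_gene_counts()
        df = ann.data.drop(columns="length").copy()
        df.loc[df["gene_id"] == "gA", "end"] = 2000  # length 1000 -> 2000
        rpkm2 = g.compute_rpkm(counts, g.GeneAnnotation(df))
        rpkm1 = g.compute_rpkm(counts, ann)
        assert rpkm2.loc["gA", "s1"] == pytest.approx(
            rpkm1.loc["gA", "s1"] / 2
        )

    def test_algebraic_inversion_recovers_column_sums(self, small_dataset):
        ann, counts, _ = small_dataset
        rpkm = g.compute_rpkm(counts, ann)
        lengths = ann.lengths().reindex(counts.gene_ids)
        spike = ann.data.set_index("gene_id")["is_spike_in"].reindex(
            counts.gene_ids
        )
        totals = counts.counts.loc[~spike.to_numpy()].sum(axis=0)
        rebuilt = rpkm.mul(lengths / 1e3, axis=0).mul(totals / 1e6, axis=1)
        np.testing.assert_allclose(
            rebuilt.to_numpy(), counts.counts.to_numpy(), rtol=1e-9
        )


class TestExpressionCutoff:
    def test_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(0)
        log2_rpkm = rng.normal(5.0, 2.0, 5000)
        cutoff = g.fit_expression_cutoff(2.0**log2_rpkm)
        # KDE mode and half-width wobble by a fraction of the bandwidth
        assert cutoff.mu == pytest.approx(5.0, abs=0.7)
        assert cutoff.sigma == pytest.approx(2.0, abs=0.5)
        assert cutoff.threshold == pytest.approx(-1.0, abs=1.5)

    def test_silent_mode_ignored_in_bimodal_mixture(self):
        rng = np.random.default_rng(1)
        silent = rng.normal(-8.0, 1.0, 1500)
        expressed = rng.normal(5.0, 2.0, 4500)
        cutoff = g.fit_expression_cutoff(2.0 ** np.concatenate([silent, expressed]))
        assert cutoff.mu == pytest.approx(5.0, abs=0.5)

    def test_all_equal_input_rejected(self):
        with pytest.raises(ValueError):
            g.fit_expression_cutoff(np.full(200, 4.0))


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 30], "s2": [10, 20, 30]}, index=["a", "b", "c"]
        )
        f = g.size_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0])

    def test_doubled_sample_scales_exactly(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=["a", "b", "c"]
        )
        f = g.size_factors(counts)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_all_zero_gene_reference_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [0, 1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            g.size_factors(counts)

    def test_spike_reference_reveals_global_inflation(self):
        # group-B mRNA inflated 1.10x: absolute (spike-in) factors differ
        # from relative factors by ~10% for group B
        cfg = g.SimulationConfig(
            n_chromosomes=3,
            genes_per_chromosome=150,
            group_sizes=(4, 4),
            duplicated_interval=None,
            block_correlation=0.0,
            sample_noise_log_sd=0.02,
            dispersion=0.02,
            spike_in=150,
            global_inflation=1.10,
            seed=11,
        )
        ann = g.make_annotation(cfg)
        counts, truth = g.simulate_counts(ann, cfg)
        spikes = list(truth.spike_in_abundances.index)
        rel = g.size_factors(counts.counts.drop(index=spikes))
        absolute = g.size_factors(counts.counts, reference_genes=spikes)
        ratio = (absolute / rel)
        b = counts.group_samples("Dp")
        a = counts.group_samples("WT")
        observed = ratio[b].mean() / ratio[a].mean()
        assert observed == pytest.approx(1 / 1.10, rel=0.04)


class TestFoldChangeProfile:
    def test_equal_group_means_give_zero_h(self, tiny_annotation):
        counts = pd.DataFrame(
            {
                "a1": [100, 200, 300],
                "a2": [100, 200, 300],
                "b1": [100, 200, 300],
                "b2": [100, 200, 300],
            },
            index=["gA", "gB", "gC"],
        )
        design = pd.Series(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        cm = g.CountMatrix(counts, design)
        prof = g.fold_change_profile(
            cm, tiny_annotation, groups=("A", "B")
        )
        np.testing.assert_allclose(prof.data["h"].to_numpy(), 0.0)

    def test_swapping_groups_negates_h(self, small_dataset):
        ann, counts, _ = small_dataset
        fwd = g.fold_change_profile(counts, ann, groups=("WT", "Dp"))
        rev = g.fold_change_profile(counts, ann, groups=("Dp", "WT"))
        np.testing.assert_allclose(
            fwd.data["h"].to_numpy(), -rev.data["h"].to_numpy(), atol=1e-12
        )

    def test_sample_scaling_absorbed_by_size_factor(self, small_dataset):
        ann, counts, _ = small_dataset
        k = 3
        scaled = counts.counts.copy()
        scaled["WT_1"] = scaled["WT_1"] * k
        cm = g.CountMatrix(scaled, counts.design)
        f0 = g.size_factors(counts)
        f1 = g.size_factors(cm)
        # relative factor of the scaled sample grows exactly k-fold
        rel0 = f0["WT_1"] / f0["WT_2"]
        rel1 = f1["WT_1"] / f1["WT_2"]
        assert rel1 / rel0 == pytest.approx(k, rel=1e-9)
        p0 = g.fold_change_profile(counts, ann, groups=("WT", "Dp"))
        p1 = g.fold_change_profile(cm, ann, groups=("WT", "Dp"))
        np.testing.assert_allclose(
            p0.data["h"].to_numpy(), p1.data["h"].to_numpy(), atol=0.02
        )

    def test_lower_cutoff_keeps_superset(self, small_dataset):
        ann, counts, _ = small_dataset
        strict = g.fold_change_profile(
            counts, ann, groups=("WT", "Dp"), cutoff=2.0
        )
        loose = g.fold_change_profile(
            counts, ann, groups=("WT", "Dp"), cutoff=-2.0
        )
        assert set(strict.data["gene_id"]) <= set(loose.data["gene_id"])

    def test_duplicated_segment_recovers_dosage(self, small_dataset, small_profile):
        _, _, truth = small_dataset
        dup = small_profile.data[
            small_profile.data["gene_id"].isin(truth.duplicated_genes)
        ]
        assert len(dup) >= 50
        fc = 2.0 ** dup["h"].to_numpy()
        assert fc.mean() == pytest.approx(1.5, abs=0.08)

    def test_profile_tsv_round_trip(self, small_profile, tmp_path):
        path = tmp_path / "profile.tsv"
        small_profile.to_tsv(path)
        back = g.FoldChangeProfile.from_tsv(path)
        pd.testing.assert_frame_equal(back.data, small_profile.data)


class TestCompareNormalizations:
    @staticmethod
    def _simulate(inflation, seed):
        cfg = g.SimulationConfig(
            n_chromosomes=4,
            genes_per_chromosome=200,
            group_sizes=(4, 4),
            duplicated_interval=None,
            block_correlation=0.0,
            sample_noise_log_sd=0.02,
            dispersion=0.01,
            spike_in=60,
            global_inflation=inflation,
            seed=seed,
        )
        ann = g.make_annotation(cfg)
        counts, truth = g.simulate_counts(ann, cfg)
        return ann, counts, list(truth.spike_in_abundances.index)

    def test_null_shift_near_zero(self):
        ann, counts, spikes = self._simulate(1.0, seed=5)
        res = g.compare_normalizations(counts, spikes, ("WT", "Dp"), ann)
        assert abs(res["shift"]) < 0.01

    def test_planted_global_inflation_recovered(self):
        ann, counts, spikes = self._simulate(1.018, seed=6)
        res = g.compare_normalizations(counts, spikes, ("WT", "Dp"), ann)
        assert res["shift"] == pytest.approx(0.018, abs=0.01)

    def test_uniform_inflation_gives_unskewed_strata(self):
        ann, counts, spikes = self._simulate(1.05, seed=8)
        res = g.compare_normalizations(counts, spikes, ("WT", "Dp"), ann)
        shifts = list(res["per_stratum"].values())
        assert len(shifts) >= 2
        assert max(shifts) - min(shifts) < 0.02


class TestStratification:
    def test_null_u_statistic_near_half_product(self):
        rng = np.random.default_rng(3)
        prof = make_profile(rng.normal(size=200), mean_rpkm=50.0)
        ctrl = make_profile(rng.normal(size=200), mean_rpkm=50.0)
        res = g.stratify_fold_changes(prof, ctrl)
        row = res[res["stratum"] == "medium"].iloc[0]
        assert row["U"] == pytest.approx(200 * 200 / 2, rel=0.1)
        assert row["p_value"] > 0.01

    def test_large_shift_detected_with_direction(self):
        rng = np.random.default_rng(4)
        prof = make_profile(rng.normal(1.0, 1.0, 200), mean_rpkm=50.0)
        ctrl = make_profile(rng.normal(0.0, 1.0, 200), mean_rpkm=50.0)
        res = g.stratify_fold_changes(prof, ctrl)
        row = res[res["stratum"] == "medium"].iloc[0]
        assert row["p_value"] < 1e-6
        assert row["median_shift"] > 0

    @pytest.mark.parametrize(
        "rpkm,stratum", [(0.1, "low"), (10.0, "medium"), (100.0, "high")]
    )
    def test_boundary_values_assigned_upward(self, rpkm, stratum):
        rng = np.random.default_rng(5)
        prof = make_profile(rng.normal(size=20), mean_rpkm=rpkm)
        ctrl = make_profile(rng.normal(size=20), mean_rpkm=rpkm)
        res = g.stratify_fold_changes(prof, ctrl)
        assert list(res["stratum"]) == [stratum]


class TestProfileCorrelation:
    def test_self_correlation_is_one(self, small_profile):
        r, n = g.profile_correlation(small_profile, small_profile)
        assert r == pytest.approx(1.0)
        assert n == len(small_profile.data[~small_profile.data["excluded"]])

    def test_negation_gives_minus_one(self, small_profile):
        r, _ = g.profile_correlation(small_profile, small_profile.negated())
        assert r == pytest.approx(-1.0)

    def test_independent_profiles_weakly_correlated(self):
        a = g.simulate_signed_profile(400, rho=0.0, sigma=1.0, seed=1)
        b = g.simulate_signed_profile(400, rho=0.0, sigma=1.0, seed=2)
        r, n = g.profile_correlation(a, b)
        assert abs(r) < 2.5 / np.sqrt(n)

    def test_zero_variance_reported_as_nan(self):
        a = make_profile(np.ones(10))
        b = make_profile(np.arange(10) - 4.5)
        r, _ = g.profile_correlation(a, b)
        assert np.isnan(r)
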