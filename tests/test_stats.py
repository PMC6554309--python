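import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

import geddscan as g
from conftest import make_profile

finite_h = hnp.arrays(
    np.float64,
    hst.integers(min_value=2, max_value=40),
    elements=hst.floats(-10, 10, allow_nan=False).filter(lambda x: x != 0),
)


class TestFlips:
    @pytest.mark.parametrize(
        "h,expected",
        [
            ([0.4, 0.1, 2.0], 0),
            ([1, -1, 1, -1, 1, -1], 5),
            ([1.2, 0.3, -0.5, 0.7, 0.2], 2),
        ],
    )
    def test_definition(self, h, expected):
        assert g.count_flips(h) == expected

    def test_zero_inherits_previous_sign(self):
        # (+, 0, -) : the zero counts as +, one flip at the last step
        assert g.count_flips([1.0, 0.0, -1.0]) == 1
        # leading zero counts as positive
        assert g.count_flips([0.0, -1.0]) == 1
        assert g.count_flips([0.0, 1.0]) == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            g.count_flips([1.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(finite_h, hst.floats(0.1, 100))
    def test_invariant_under_sign_flip_and_rescaling(self, h, c):
        f = g.count_flips(h)
        assert g.count_flips(-h) == f
        assert g.count_flips(c * h) == f


class TestEnergy:
    def test_hand_evaluated_examples(self):
        # E = sum h_i h_{i-1} + h_i h_{i+1}, missing neighbours -> 0
        assert g.energy([1, 1, 1]) == pytest.approx(4.0)
        assert g.energy([1, -1, 1]) == pytest.approx(-4.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(finite_h, hst.floats(0.1, 10))
    def test_parity_and_quadratic_homogeneity(self, h, c):
        e = g.energy(h)
        assert g.energy(-h) == pytest.approx(e, rel=1e-9, abs=1e-9)
        assert g.energy(c * h) == pytest.approx(c * c * e, rel=1e-6, abs=1e-6)


class TestPermutationNull:
    @pytest.mark.parametrize("n_pos,n_neg", [(50, 50), (30, 70), (10, 90)])
    def test_flips_null_matches_runs_test_closed_form(self, n_pos, n_neg):
        # Wald-Wolfowitz run-count moments (F = R - 1) are an analytic
        # oracle for the permutation engine
        rng = np.random.default_rng(42)
        h = np.concatenate(
            [rng.uniform(0.1, 2, n_pos), rng.uniform(-2, -0.1, n_neg)]
        )
        rng.shuffle(h)
        n_perm = 20_000
        null = g.permutation_null(h, "flips", n_perm, seed=9)
        mean, sd = g.runs_null_moments(n_pos, n_neg)
        se_mean = sd / np.sqrt(n_perm)
        assert abs(null.mean - mean) < 4 * se_mean
        se_sd = sd / np.sqrt(2 * (n_perm - 1))
        assert abs(null.sd - sd) < 4 * se_sd

    def test_constant_sign_flips_null_degenerate(self):
        h = np.array([0.5, 1.2, 0.3, 2.0, 0.8])
        null = g.permutation_null(h, "flips", 500, seed=0)
        assert null.mean == 0.0 and null.sd == 0.0
        assert null.degenerate

    def test_same_seed_reproducible(self):
        h = np.random.default_rng(3).normal(size=50)
        a = g.permutation_null(h, "energy", 1000, seed=11)
        b = g.permutation_null(h, "energy", 1000, seed=11)
        assert a.mean == b.mean and a.sd == b.sd

    def test_energy_null_mean_matches_exchangeable_expectation(self):
        # E[E_perm] = 2 (N-1) * (sum_{i!=j} h_i h_j) / (N (N-1))
        h = np.random.default_rng(7).normal(size=60)
        null = g.permutation_null(h, "energy", 20_000, seed=2)
        s1, s2 = h.sum(), (h**2).sum()
        expected = 2 * (s1**2 - s2) / len(h)
        assert null.mean == pytest.approx(
            expected, abs=4 * null.sd / np.sqrt(20_000)
        )


class TestChromosomeTest:
    def test_strong_autocorrelation_flagged_both_metrics(self):
        for seed in range(3):
            prof = g.simulate_signed_profile(500, rho=0.95, sigma=0.5, seed=seed)
            res = g.test_chromosome(
                prof, n_permutations=2000, sd_threshold=2.0, seed=seed
            )
            assert res.flips_significant is True
            assert res.energy_significant is True

    def test_infinite_threshold_never_significant(self):
        prof = g.simulate_signed_profile(200, rho=0.9, sigma=0.5, seed=0)
        res = g.test_chromosome(
            prof, n_permutations=500, sd_threshold=np.inf, seed=0
        )
        assert res.flips_significant is False
        assert res.energy_significant is False

    def test_degenerate_null_yields_no_call(self):
        res = g.test_chromosome(
            np.abs(np.random.default_rng(0).normal(size=30)) + 0.1,
            n_permutations=500,
            seed=0,
        )
        assert res.flips_degenerate
        assert res.flips_significant is None

    def test_directionality_of_calls(self):
        # clustered profile: flips depressed (z<0), energy elevated (z>0)
        prof = g.simulate_signed_profile(400, rho=0.9, sigma=0.5, seed=5)
        res = g.test_chromosome(prof, n_permutations=2000, seed=5)
        assert res.flips_z < 0
        assert res.energy_z > 0


class TestScanGenome:
    def test_null_scan_rarely_flags(self):
        # 20 i.i.d. chromosomes: expected flags per metric ~20 x 2.3%
        rng = np.random.default_rng(12)
        import pandas as pd

        frames = []
        for c in range(20):
            p = make_profile(rng.normal(size=150), chrom=f"chr{c + 1:02d}")
            frames.append(p.data)
        profile = g.FoldChangeProfile(pd.concat(frames))
        scan = g.scan_genome(profile, n_permutations=1000, seed=3)
        assert scan.n_flips_significant <= 3
        assert scan.n_energy_significant <= 3

    def test_planted_clustering_flagged_by_energy(self):
        import pandas as pd

        frames = []
        for c in range(8):
            rho = 0.9 if c < 4 else 0.0
            p = g.simulate_signed_profile(
                300, rho=rho, sigma=0.5, seed=100 + c, chrom=f"chr{c + 1}"
            )
            frames.append(p.data)
        profile = g.FoldChangeProfile(pd.concat(frames))
        scan = g.scan_genome(profile, n_permutations=2000, seed=4)
        table = scan.table.set_index("chrom")
        planted = [f"chr{i + 1}" for i in range(4)]
        assert table.loc[planted, "energy_sig"].sum() >= 3
        assert table.loc[planted, "flips_sig"].sum() >= 3

    def test_monotone_power_in_autocorrelation(self):
        rates = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            flags = 0
            for seed in range(8):
                prof = g.simulate_signed_profile(
                    250, rho=rho, sigma=0.5, seed=1000 + seed
                )
                res = g.test_chromosome(prof, n_permutations=1000, seed=seed)
                flags += bool(res.energy_significant)
            rates.append(flags / 8)
        assert rates == sorted(rates)
        assert rates[-1] > rates[0]

    def test_excluded_genes_left_out_of_statistics(self):
        h = np.array([1.0, 1.0, -5.0, 1.0, 1.0, 1.0])
        excl = np.array([False, False, True, False, False, False])
        prof = make_profile(h, excluded=excl)
        assert g.count_flips(prof.h_values("chr1")) == 0
        assert len(prof.h_values("chr1")) == 5

    def test_empty_profile_rejected(self):
        import pandas as pd

        with pytest.raises(Exception):
            g.scan_genome(
                g.FoldChangeProfile(
                    pd.DataFrame(
                        columns=[
                            "gene_id",
                            "chrom",
                            "start",
                            "end",
                            "midpoint",
                            "h",
                            "mean_rpkm",
                            "excluded",
                        ]
                    )
                ),
                n_permutations=500,
            )

    def test_scan_reproducible_and_summary_consistent(self, small_profile):
        a = g.scan_genome(small_profile, n_permutations=500, seed=21)
        b = g.scan_genome(small_profile, n_permutations=500, seed=21)
        assert a.table.equals(b.table)
        assert a.n_flips_significant == int(a.table["flips_sig"].sum())
        assert a.n_energy_significant == int(a.table["energy_sig"].sum())
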