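import numpy as np
import pandas as pd
import pytest

from rhoscape import (
    CrossoverTable,
    HaplotypeBlock,
    RhoLandscape,
    diversity_binned_co_rate,
    rho_binned_co_rate,
    theta_pi_windows,
)


def _cos(intervals, n_individuals=108, chrom="chr1"):
    df = pd.DataFrame(intervals, columns=["start", "end"])
    df.insert(0, "chromosome", chrom)
    df["offspring_id"] = [f"o{i}" for i in range(len(df))]
    return CrossoverTable(df, n_individuals=n_individuals)


class TestRhoBinnedRate:
    def test_worked_example_100_cm_mb(self):
        """10^6 bp and 108 COs in one bin with 108 individuals -> 100 cM/Mb."""
        lands = RhoLandscape.from_intervals("chr1", [(0, 1_000_000, 0.01)])
        cos = _cos([(i * 9000, i * 9000 + 100) for i in range(108)])
        df = rho_binned_co_rate(lands, cos, n_bins=50, rho_range=(0, 0.06))
        used = df[df["bp"] > 0]
        assert len(used) == 1
        assert used["co_count"].iloc[0] == 108
        assert used["cm_per_mb"].iloc[0] == pytest.approx(100.0)

    def test_zero_co_bin_rate_zero(self):
        lands = RhoLandscape.from_intervals(
            "chr1", [(0, 500_000, 0.01), (500_000, 1_000_000, 0.03)])
        cos = _cos([(1000, 1100)])  # midpoint in the 0.01 bin
        df = rho_binned_co_rate(lands, cos, n_bins=50)
        in_003 = df[(df["bin_lo"] <= 0.03) & (df["bin_hi"] > 0.03)]
        assert in_003["co_count"].iloc[0] == 0
        assert in_003["cm_per_mb"].iloc[0] == 0.0

    def test_halving_bp_doubles_rate(self):
        cos = _cos([(100, 200)] * 10)
        big = RhoLandscape.from_intervals("chr1", [(0, 1_000_000, 0.01)])
        small = RhoLandscape.from_intervals("chr1", [(0, 500_000, 0.01)])
        r_big = rho_binned_co_rate(big, cos)
        r_small = rho_binned_co_rate(small, cos)
        v_big = r_big.loc[r_big["bp"] > 0, "cm_per_mb"].iloc[0]
        v_small = r_small.loc[r_small["bp"] > 0, "cm_per_mb"].iloc[0]
        assert v_small == pytest.approx(2 * v_big)

    def test_overflow_bin_reported_and_flagged(self):
        lands = RhoLandscape.from_intervals("chr1", [(0, 10_000, 0.5)])
        cos = _cos([(100, 200)])
        df = rho_binned_co_rate(lands, cos, rho_range=(0, 0.06))
        over = df[df["overflow"]]
        assert over["bp"].iloc[0] == 10_000
        assert over["co_count"].iloc[0] == 1

    def test_counts_conserved_including_unassigned(self):
        lands = RhoLandscape.from_intervals("chr1", [(0, 10_000, 0.01)])
        cos = _cos([(100, 200), (20_000, 20_100)])  # second is uncovered
        df = rho_binned_co_rate(lands, cos)
        assert df["co_count"].sum() + df.attrs["unassigned_cos"] == len(cos)
        assert df.attrs["unassigned_cos"] == 1

    def test_zero_bp_bin_flagged_nan(self):
        lands = RhoLandscape.from_intervals("chr1", [(0, 10_000, 0.01)])
        df = rho_binned_co_rate(lands, _cos([(100, 200)]))
        empty = df[(df["bp"] == 0) & ~df["overflow"]]
        assert empty["cm_per_mb"].isna().all()


def _block_one_snp(n=4, L=20_000, pos=500, derived=2):
    geno = np.zeros((n, 1), dtype=np.int8)
    geno[:derived, 0] = 1
    return HaplotypeBlock(chromosome="chr1", positions=np.array([pos]),
                          genotypes=geno, ref=np.array(["A"]),
                          alt=np.array(["G"]), sequence_length=L)


class TestThetaPi:
    def test_monomorphic_window_zero(self):
        block = _block_one_snp(derived=2)
        silent = np.ones(20_000, dtype=bool)
        silent[490:510] = False  # exclude the SNP: no silent polymorphism
        df = theta_pi_windows(block, silent, window=10_000, min_silent=500)
        assert df["theta_pi"].iloc[0] == 0.0

    def test_hand_computed_single_snp(self):
        """4 haplotypes, 1 silent SNP at 2/4, 1000 silent sites ->
        (2*2/C(4,2))/1000 = 6.67e-4."""
        block = _block_one_snp(n=4, L=10_000, pos=500, derived=2)
        silent = np.zeros(10_000, dtype=bool)
        silent[:1000] = True
        df = theta_pi_windows(block, silent, window=10_000, min_silent=500)
        assert df["theta_pi"].iloc[0] == pytest.approx((4 / 6) / 1000)

    def test_window_below_min_silent_dropped(self):
        block = _block_one_snp(L=10_000)
        silent = np.zeros(10_000, dtype=bool)
        silent[:400] = True
        df = theta_pi_windows(block, silent, window=10_000, min_silent=500)
        assert len(df) == 0

    def test_matches_brute_force_all_pairs(self):
        """Window theta_pi equals the all-pairs Hamming computation on small
        complete-data instances."""
        rng = np.random.default_rng(9)
        for trial in range(5):
            n, s, L = 8, 60, 5000
            geno = (rng.random((n, s)) < rng.uniform(0.1, 0.5)).astype(np.int8)
            positions = np.sort(rng.choice(L, s, replace=False))
            block = HaplotypeBlock(chromosome="chr1", positions=positions,
                                   genotypes=geno, ref=np.full(s, "A"),
                                   alt=np.full(s, "G"), sequence_length=L)
            silent = np.ones(L, dtype=bool)
            df = theta_pi_windows(block, silent, window=L, min_silent=1)
            brute = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    brute += np.sum(geno[i] != geno[j])
            brute /= (n * (n - 1) / 2) * L
            assert df["theta_pi"].iloc[0] == pytest.approx(brute, abs=1e-12)


class TestDiversityBinnedRate:
    def _windows(self, pis, width=10_000):
        starts = np.arange(len(pis)) * width
        return pd.DataFrame({
            "chromosome": "chr1", "start": starts, "end": starts + width,
            "silent_sites": 5000, "theta_pi": pis,
        })

    def test_constructed_association_positive_slope(self):
        rng = np.random.default_rng(0)
        pis = np.linspace(0.005, 0.095, 50)
        wins = self._windows(pis)
        # place COs proportional to diversity
        intervals = []
        for i, pi in enumerate(pis):
            k = rng.poisson(40 * pi)
            intervals += [(i * 10_000 + 100, i * 10_000 + 200)] * k
        cos = _cos(intervals)
        df, fit = diversity_binned_co_rate(wins, cos, n_bins=10,
                                           pi_range=(0, 0.1), min_bin_bp=10_000)
        assert fit is not None
        assert fit.slope > 0
        assert fit.r_squared > 0.5

    def test_uniform_placement_flat_slope(self):
        pis = np.linspace(0.005, 0.095, 50)
        wins = self._windows(pis)
        cos = _cos([(i * 10_000 + 100, i * 10_000 + 200) for i in range(50)] * 2)
        df, fit = diversity_binned_co_rate(wins, cos, n_bins=10,
                                           pi_range=(0, 0.1), min_bin_bp=10_000)
        # equal counts per equal-bp bin: regression of rate on pi is flat
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_small_bins_discarded(self):
        pis = np.array([0.011] * 30 + [0.055])  # one lone window in its bin
        wins = self._windows(pis)
        cos = _cos([(100, 200)])
        df, _ = diversity_binned_co_rate(wins, cos, n_bins=10, pi_range=(0, 0.1),
                                         min_bin_bp=200_000)
        lone = df[(df["bin_lo"] <= 0.055) & (df["bin_hi"] > 0.055)]
        assert not lone["retained"].iloc[0]

    def test_co_assignment_uses_overlapping_windows_only(self):
        wins = self._windows(np.array([0.01, 0.05]))
        # CO spanning only the second window
        cos = _cos([(12_000, 13_000)])
        df, _ = diversity_binned_co_rate(wins, cos, n_bins=10, pi_range=(0, 0.1),
                                         min_bin_bp=1)
        hit = df[(df["bin_lo"] <= 0.05) & (df["bin_hi"] > 0.05)]
        assert hit["co_count"].iloc[0] == 1
        assert df.attrs["unassigned_cos"] == 0
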