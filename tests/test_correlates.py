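import itertools

import numpy as np
import pandas as pd
import pytest

from rhoscape import (
    RhoLandscape,
    annotation_rho,
    annotation_tracts,
    classify_sites,
    gc_content_windows,
    gc_rho_correlation,
    generate_annotation,
    mann_whitney_rho,
    rho_density_regression,
)
from rhoscape.correlates import AnnotationError


def _write_gff(path, genome_length, genes):
    """genes: list of (start1, end1, strand, children) with 1-based inclusive
    coordinates; children: list of (type, start1, end1)."""
    lines = ["##gff-version 3", f"##sequence-region chr1 1 {genome_length}"]
    for i, (s, e, strand, children) in enumerate(genes):
        lines.append(f"chr1\ttest\tgene\t{s}\t{e}\t.\t{strand}\t.\tID=g{i}")
        lines.append(f"chr1\ttest\tmRNA\t{s}\t{e}\t.\t{strand}\t.\tID=g{i}.t;Parent=g{i}")
        for j, (t, cs, ce) in enumerate(children):
            lines.append(f"chr1\ttest\t{t}\t{cs}\t{ce}\t.\t{strand}\t.\t"
                         f"ID=g{i}.t.{j};Parent=g{i}.t")
    path.write_text("\n".join(lines) + "\n")


class TestClassifySites:
    def test_tract_between_genes_coordinates(self, tmp_path):
        # gene A occupies 1..1000, gene B 4001..5000 (1-based inclusive)
        gff = tmp_path / "t.gff3"
        _write_gff(gff, 10_000, [
            (1, 1000, "+", [("CDS", 1, 1000)]),
            (4001, 5000, "+", [("CDS", 4001, 5000)]),
        ])
        mask = classify_sites(gff, {"chr1": 10_000})
        t = mask.tracts
        middle = t[(t["start"] == 1000) & (t["end"] == 4000)]
        assert len(middle) == 1
        assert middle["length"].iloc[0] == 3000
        assert middle["length_class"].iloc[0] == "long"
        prox = mask.gene_proximal_mask("chr1")
        assert prox[1000:4000].all()  # 3000 < 2x2000: whole tract proximal
        assert prox[5500]        # within 2 kb of gene B's right edge
        assert not prox[8000]    # mid-tract, no gene within 2 kb (right end is
        # the chromosome edge, not a gene)

    def test_short_tract_binned_short(self, tmp_path):
        gff = tmp_path / "t.gff3"
        _write_gff(gff, 6000, [
            (1, 2000, "+", [("CDS", 1, 2000)]),
            (3001, 5000, "+", [("CDS", 3001, 5000)]),
        ])
        mask = classify_sites(gff, {"chr1": 6000})
        t = mask.tracts
        assert t[(t["start"] == 2000)]["length_class"].iloc[0] == "short"

    def test_precedence_cds_over_utr_over_intron(self, tmp_path):
        gff = tmp_path / "t.gff3"
        _write_gff(gff, 3000, [
            (1, 2000, "+", [
                ("five_prime_UTR", 1, 200),
                ("CDS", 150, 1000),       # overlaps the UTR: CDS wins
                ("three_prime_UTR", 1800, 2000),
            ]),
        ])
        mask = classify_sites(gff, {"chr1": 3000})
        lab = mask.label_array("chr1")
        from rhoscape.correlates import _LABEL_CODE

        assert lab[100] == _LABEL_CODE["UTR5"]
        assert lab[200] == _LABEL_CODE["CDS"]   # overlap resolved to CDS
        assert lab[1200] == _LABEL_CODE["intron"]
        assert lab[1900] == _LABEL_CODE["UTR3"]
        assert lab[2500] == _LABEL_CODE["intergenic"]

    def test_partition_invariant_on_generated_annotation(self, tmp_path):
        gff = tmp_path / "g.gff3"
        generate_annotation(200_000, seed=8, out_gff=gff)
        mask = classify_sites(gff, {"chr1": 200_000})
        counts = mask.bp_counts()
        assert sum(counts.values()) == 200_000

    def test_feature_beyond_chromosome_reported(self, tmp_path):
        gff = tmp_path / "t.gff3"
        _write_gff(gff, 500, [(1, 1000, "+", [("CDS", 1, 1000)])])
        with pytest.raises(AnnotationError, match="beyond chromosome end"):
            classify_sites(gff, {"chr1": 500})


class TestAnnotationRho:
    def _mask(self, tmp_path, L=20_000):
        gff = tmp_path / "g.gff3"
        generate_annotation(L, seed=2, out_gff=gff)
        return classify_sites(gff, {"chr1": L})

    def test_constant_landscape_zero_width_ci(self, tmp_path):
        L = 20_000
        mask = self._mask(tmp_path, L)
        lands = RhoLandscape.from_intervals("chr1", [(0, L, 0.004)])
        table = annotation_rho(mask, lands, n_boot=100, seed=0)
        used = table.dropna(subset=["mean_rho"])
        assert np.allclose(used["mean_rho"], 0.004)
        assert np.allclose(used["ci_low"], used["ci_high"])

    def test_painted_label_means_exact(self, tmp_path):
        L = 20_000
        mask = self._mask(tmp_path, L)
        genic = mask.genic_mask("chr1")
        rho = np.where(genic, 0.002, 0.006)
        edges = np.flatnonzero(np.diff(rho)) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [L]])
        lands = RhoLandscape.from_intervals(
            "chr1", np.column_stack([starts, ends, rho[starts]]))
        table = annotation_rho(mask, lands, n_boot=50, seed=0).set_index("category")
        assert table.loc["genic", "mean_rho"] == pytest.approx(0.002)
        assert table.loc["intergenic", "mean_rho"] == pytest.approx(0.006)
        assert table.loc["CDS", "mean_rho"] == pytest.approx(0.002)

    def test_bootstrap_ci_coverage(self):
        """Percentile bootstrap CI covers the generating mean ~95% of the
        time (>=90/100 draws)."""
        from rhoscape.correlates import _bootstrap_ci

        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            values = rng.gamma(2.0, 0.002, size=300)
            lo, hi = _bootstrap_ci(values, 300, rng)
            hits += lo <= 2.0 * 0.002 <= hi
        assert hits >= 90


class TestRegression:
    def _tracts(self, beta_ann=0.3, beta_dens=0.05, n=60, dens=None):
        rng = np.random.default_rng(1)
        ann = np.array(["intron", "CDS"] * (n // 2))
        dens = rng.uniform(0.01, 0.1, n) if dens is None else np.full(n, dens)
        rho = 0.001 + beta_ann * (ann == "CDS") + beta_dens * dens
        return pd.DataFrame({"annotation": ann, "snp_density": dens, "rho": rho})

    def test_exact_recovery_without_noise(self):
        res = rho_density_regression(self._tracts())
        assert res.params["C(annotation)[T.intron]"] == pytest.approx(-0.3, abs=1e-8)
        assert res.params["snp_density"] == pytest.approx(0.05, abs=1e-8)
        assert not res.dropped_interaction
        assert res.standardized_params is not None

    def test_null_coefficients_near_zero(self):
        rng = np.random.default_rng(2)
        df = self._tracts(beta_ann=0.0, beta_dens=0.0)
        df["rho"] = rng.normal(0.004, 0.001, len(df))
        res = rho_density_regression(df)
        assert abs(res.params["C(annotation)[T.intron]"]) < 0.002
        assert res.pvalues["C(annotation)[T.intron]"] > 0.01

    def test_constant_density_drops_interaction(self):
        res = rho_density_regression(self._tracts(dens=0.05))
        assert res.dropped_interaction
        assert "snp_density" not in res.params.index

    def test_tract_extraction_from_mask(self, tmp_path):
        gff = tmp_path / "g.gff3"
        generate_annotation(30_000, seed=3, out_gff=gff)
        mask = classify_sites(gff, {"chr1": 30_000})
        lands = RhoLandscape.from_intervals("chr1", [(0, 30_000, 0.004)])
        tracts = annotation_tracts(mask, lands, {"chr1": np.arange(0, 30_000, 40)})
        assert (tracts["end"] - tracts["start"]).sum() == 30_000
        assert np.allclose(tracts["rho"], 0.004)
        assert np.allclose(tracts["snp_density"], 1 / 40, atol=2e-3)


class TestGC:
    def test_all_g_window(self):
        assert gc_content_windows("G" * 100, 100)["gc"].iloc[0] == 1.0

    def test_acgt_repeat_half(self):
        assert gc_content_windows("ACGT" * 250, 1000)["gc"].iloc[0] == 0.5

    def test_n_bases_excluded(self):
        df = gc_content_windows("GGNNAA", 6)
        assert df["gc"].iloc[0] == pytest.approx(0.5)

    def test_monotone_gc_rho_gives_spearman_one(self):
        rng = np.random.default_rng(0)
        rhos = np.sort(rng.uniform(0.0005, 0.05, 20))
        lands = RhoLandscape.from_intervals(
            "chr1", [(i * 2000, (i + 1) * 2000, r) for i, r in enumerate(rhos)])
        seq = "".join(
            "G" * int(2000 * (0.3 + 0.4 * i / 19)) +
            "A" * (2000 - int(2000 * (0.3 + 0.4 * i / 19)))
            for i in range(20))
        rho_s, p, _ = gc_rho_correlation(seq, lands, window=2000)
        assert rho_s == pytest.approx(1.0)
        assert p < 1e-6


class TestMannWhitney:
    def test_u_statistic_matches_brute_force(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 0.01, 9)
        b = rng.uniform(0, 0.01, 7)
        u, _ = mann_whitney_rho(a, b)
        brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert u == pytest.approx(brute)

    def test_exact_p_matches_permutation_enumeration(self):
        a = np.array([0.001, 0.004, 0.009])
        b = np.array([0.002, 0.003, 0.011, 0.015])
        _, p = mann_whitney_rho(a, b)
        pooled = np.concatenate([a, b])
        n_a = len(a)

        def u_stat(ia):
            av = pooled[list(ia)]
            bv = np.delete(pooled, list(ia))
            return sum((x > y) + 0.5 * (x == y) for x in av for y in bv)

        obs = u_stat(range(n_a))
        null = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n_a)]
        centre = n_a * (len(pooled) - n_a) / 2
        extreme = np.mean([abs(u - centre) >= abs(obs - centre) - 1e-12 for u in null])
        assert p == pytest.approx(extreme, abs=1e-9)
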