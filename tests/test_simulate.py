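import numpy as np
import pytest
import scipy.stats

from rhoscape import (
    CrossoverTable,
    HaplotypeBlock,
    InfeasiblePlacementError,
    SimConfig,
    TruthRecMap,
    build_truth_map,
    estimate_matrix,
    generate_annotation,
    generate_crossovers,
    generate_genome_sequence,
    generate_ma_mutations,
    load_printed_matrix,
    simulate_haplotypes,
)


class TestTruthMap:
    def test_default_config_plants_eight_2kb_hotspots(self):
        tm = build_truth_map(SimConfig(seed=0))
        assert len(tm.hotspots) == 8
        assert sum(e - s for s, e, _ in tm.hotspots) == 16_000
        assert sorted(f for _, _, f in tm.hotspots) == [10, 10, 20, 20, 40, 40, 60, 60]
        # segments tile [0, L) (validated on construction) and hotspots sit
        # at background x fold
        for s, e, f in tm.hotspots:
            assert tm.rho_at([s])[0] == pytest.approx(0.001 * f)

    def test_empty_spec_gives_uniform_map(self):
        tm = build_truth_map(SimConfig(hotspot_spec=(), seed=0))
        assert tm.segments == [(0, 1_000_000, 0.001)]
        assert tm.hotspots == []

    def test_single_hotspot_rho_product(self):
        tm = build_truth_map(SimConfig(hotspot_spec=((2000, 10.0),), seed=3))
        (s, e, f) = tm.hotspots[0]
        assert e - s == 2000
        assert tm.rho_at([s])[0] == pytest.approx(0.01)

    def test_infeasible_placement_raises(self):
        with pytest.raises(InfeasiblePlacementError):
            build_truth_map(SimConfig(seq_length=10_000,
                                      hotspot_spec=((6000, 10.0), (6000, 10.0)),
                                      seed=0))

    def test_placement_is_seeded_and_random(self):
        a = build_truth_map(SimConfig(seed=5))
        b = build_truth_map(SimConfig(seed=5))
        c = build_truth_map(SimConfig(seed=6))
        assert a.hotspots == b.hotspots
        assert a.hotspots != c.hotspots

    def test_tsv_round_trip(self, tmp_path):
        tm = build_truth_map(SimConfig(seed=1))
        tm.to_tsv(tmp_path / "map.tsv")
        back = TruthRecMap.from_tsv(tmp_path / "map.tsv")
        assert back.segments == tm.segments
        assert back.hotspots == tm.hotspots


class TestSimulateHaplotypes:
    def test_mean_diversity_is_unbiased(self):
        """E(pi) = theta under the coalescent; Monte-Carlo over 20 seeds."""
        pis = []
        for seed in range(20):
            cfg = SimConfig(seq_length=100_000, hotspot_spec=(), seed=seed)
            pis.append(simulate_haplotypes(cfg).pairwise_diversity())
        pis = np.array(pis)
        se = pis.std(ddof=1) / np.sqrt(len(pis))
        assert abs(pis.mean() - 0.03) < 3 * se

    def test_low_mutation_limit_still_valid_vcf(self, tmp_path):
        cfg = SimConfig(seq_length=10_000, theta=0.0001, hotspot_spec=(), seed=2)
        block = simulate_haplotypes(cfg, out_vcf=tmp_path / "low.vcf")
        back = HaplotypeBlock.read_vcf(tmp_path / "low.vcf")
        assert np.array_equal(back.genotypes, block.genotypes)
        assert back.n_sites < 50

    def test_same_seed_byte_identical_vcf(self, tmp_path):
        cfg = SimConfig(seq_length=50_000, seed=7)
        simulate_haplotypes(cfg, out_vcf=tmp_path / "a.vcf")
        simulate_haplotypes(SimConfig(seq_length=50_000, seed=7),
                            out_vcf=tmp_path / "b.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_derived_alleles_follow_matrix_support(self):
        # degenerate matrix: A-ancestral sites can only mutate to T
        probs = np.eye(4)
        probs[0] = [0, 0, 0, 1]
        from rhoscape import MutationMatrix

        # rows C,G,T need off-diagonal mass to be usable; give them uniform
        for i in (1, 2, 3):
            probs[i] = [1 / 3 if j != i else 0 for j in range(4)]
        m = MutationMatrix(probs)
        cfg = SimConfig(seq_length=20_000, hotspot_spec=(), seed=3)
        block = simulate_haplotypes(cfg, mutation_matrix=m)
        a_sites = block.ref == "A"
        assert a_sites.sum() > 10
        assert np.all(block.alt[a_sites] == "T")


class TestAnnotation:
    def test_realized_genic_fraction_close_to_request(self):
        ann = generate_annotation(1_000_000, genic_fraction=0.858, seed=1)
        assert 0.838 <= ann.genic_fraction <= 0.878

    def test_single_gene_layout_has_two_tracts(self):
        ann = generate_annotation(50_000, genic_fraction=0.9, n_genes=1, seed=0)
        tracts = ann.intergenic_tracts()
        assert len(tracts) == 2
        assert len(ann.genes) == 1

    def test_fixed_seed_identical_gff(self, tmp_path):
        generate_annotation(100_000, seed=4, out_gff=tmp_path / "a.gff3")
        generate_annotation(100_000, seed=4, out_gff=tmp_path / "b.gff3")
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_tract_length_distribution_shape(self):
        """Median tract ~142 bp and ~91% below 2 kb, as configured."""
        ann = generate_annotation(2_000_000, seed=9)
        lengths = ann.intergenic_tracts().eval("end - start")
        assert 80 <= lengths.median() <= 260
        assert (lengths < 2000).mean() > 0.80


class TestCrossovers:
    @pytest.fixture()
    def uniform_map(self):
        return build_truth_map(SimConfig(seq_length=1_000_000, hotspot_spec=(), seed=0))

    def test_zero_rate_gives_zero_crossovers(self, uniform_map):
        cos = generate_crossovers(uniform_map, n_offspring=108, r_scale=0.0, seed=1)
        assert len(cos) == 0

    def test_invalid_offspring_count(self, uniform_map):
        with pytest.raises(ValueError):
            generate_crossovers(uniform_map, n_offspring=0, seed=1)

    def test_uniform_map_midpoints_uniform(self, uniform_map):
        pvals = []
        for seed in range(5):
            cos = generate_crossovers(uniform_map, n_offspring=2000,
                                      r_scale=12.0, seed=seed)
            mids = cos.midpoints() / 1_000_000
            pvals.append(scipy.stats.kstest(mids, "uniform").pvalue)
        # not extreme at alpha = 0.01 across seeds
        assert min(pvals) > 0.01 / len(pvals)

    def test_hotspot_attracts_expected_fraction(self):
        # one 10x hotspot over 10% of the genome: expected CO fraction
        # = 10*0.1 / (10*0.1 + 0.9) ~ 0.5263
        L = 100_000
        tm = TruthRecMap("chr1", [(0, 45_000, 0.001),
                                  (45_000, 55_000, 0.01),
                                  (55_000, L, 0.001)],
                         hotspots=[(45_000, 55_000, 10.0)])
        cos = generate_crossovers(tm, n_offspring=20_000, r_scale=50.0,
                                  interval_width=2, seed=3)
        mids = cos.midpoints()
        frac = ((mids >= 45_000) & (mids < 55_000)).mean()
        expected = (10 * 0.1) / (10 * 0.1 + 0.9)
        se = np.sqrt(expected * (1 - expected) / len(cos))
        assert abs(frac - expected) < 3 * se

    def test_mean_count_matches_map_length(self, uniform_map):
        cos = generate_crossovers(uniform_map, n_offspring=5000, r_scale=12.0, seed=4)
        lam = 12.0 * 1e-8 * 1_000_000  # 0.12 per offspring
        se = np.sqrt(lam / 5000)
        assert abs(len(cos) / 5000 - lam) < 4 * se

    def test_tsv_round_trip(self, uniform_map, tmp_path):
        cos = generate_crossovers(uniform_map, n_offspring=108, seed=5)
        cos.write_tsv(tmp_path / "co.tsv")
        back = CrossoverTable.read_tsv(tmp_path / "co.tsv", n_individuals=108)
        assert back.df.equals(cos.df)


class TestMAMutations:
    def test_single_mutation_valid(self):
        (anc, der), = generate_ma_mutations(load_printed_matrix(), 1, seed=0)
        assert anc in "ACGT" and der in "ACGT" and anc != der

    def test_degenerate_row_forces_transition(self):
        from rhoscape import MutationMatrix

        probs = np.array([
            [0, 0, 0, 1.0],
            [1 / 3, 0, 1 / 3, 1 / 3],
            [1 / 3, 1 / 3, 0, 1 / 3],
            [1 / 3, 1 / 3, 1 / 3, 0],
        ])
        muts = generate_ma_mutations(MutationMatrix(probs), 400, seed=1)
        a_muts = [d for a, d in muts if a == "A"]
        assert len(a_muts) > 50
        assert set(a_muts) == {"T"}

    def test_parameter_recovery_at_study_size(self):
        """5,710 sampled mutations re-estimate the generating off-diagonal
        profiles within binomial 99% bounds (joint over the 12 off-diagonal
        cells, Sidak-adjusted so the whole check has 99% coverage)."""
        matrix = load_printed_matrix()
        muts = generate_ma_mutations(matrix, 5710, seed=42)
        est = estimate_matrix(muts)
        truth = matrix.offdiagonal_rows()
        counts = np.zeros(4)
        for a, _ in muts:
            counts["ACGT".index(a)] += 1
        z = scipy.stats.norm.ppf(1 - (1 - 0.99 ** (1 / 12)) / 2)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert est.probs[i, j] == 0
                    continue
                p = truth[i, j]
                half = z * np.sqrt(p * (1 - p) / counts[i])
                assert abs(est.probs[i, j] - p) <= half + 1e-9


def test_genome_sequence_gc_control():
    seq = generate_genome_sequence(50_000, gc=0.64, seed=0)
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert gc == pytest.approx(0.64, abs=0.02)
    prof = generate_genome_sequence(30_000, seed=1,
                                    gc_profile=(10_000, np.array([0.2, 0.5, 0.8])))
    gcs = [(prof[i * 10_000:(i + 1) * 10_000].count("G")
            + prof[i * 10_000:(i + 1) * 10_000].count("C")) / 10_000
           for i in range(3)]
    assert gcs[0] < gcs[1] < gcs[2]
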