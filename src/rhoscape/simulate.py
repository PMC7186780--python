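"""Synthetic data generation: coalescent haplotypes under known
recombination maps, gene-dense annotations, crossover tables, and
mutation-accumulation style mutation lists.

Every generator keeps its ground truth (the recombination map, the planted
hotspots, the realized annotation) so downstream estimators can be scored
against what was actually simulated. Defaults emulate a facultatively
sexual green-alga population sample: 19 haploid genomes, per-bp diversity
θ ≈ 0.03, a piecewise-constant recombination map with kb-scale hotspots of
10–60× background, an ~86% genic annotation with mostly sub-2-kb
intergenic tracts, and 108 meiotic offspring carrying map-proportional
crossovers.

Scaling note: haplotypes are simulated with a haploid coalescent whose
population size is fixed at 1/2, so the per-bp mutation rate equals θ=2Nₑμ
and the per-bp recombination rate equals ρ=2Nₑr directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .haplotypes import BASES, HaplotypeBlock
from .mutmat import MutationMatrix, load_printed_matrix

#: two hotspots each at 10x, 20x, 40x and 60x background, 2 kb long
DEFAULT_HOTSPOT_SPEC = (
    (2000, 10.0), (2000, 10.0),
    (2000, 20.0), (2000, 20.0),
    (2000, 40.0), (2000, 40.0),
    (2000, 60.0), (2000, 60.0),
)


class InfeasiblePlacementError(ValueError):
    """Hotspots cannot be placed without overlap in the given length."""


@dataclass
class SimConfig:
    """Study conditions for one simulated chromosome."""

    n_samples: int = 19
    seq_length: int = 1_000_000
    theta: float = 0.03
    background_rho: float = 0.001
    hotspot_spec: tuple = DEFAULT_HOTSPOT_SPEC
    seed: int | None = None
    chromosome: str = "chr1"

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.seq_length <= 0:
            raise ValueError("seq_length must be positive")
        if self.background_rho < 0:
            raise ValueError("background_rho must be non-negative")
        for length, fold in self.hotspot_spec:
            if length <= 0 or fold <= 1:
                raise ValueError("hotspots need positive length and fold > 1")


@dataclass
class TruthRecMap:
    """Ground-truth piecewise-constant recombination map.

    ``segments`` tile [0, length) without gaps or overlaps; ``hotspots``
    records the planted (start, end, fold) intervals.
    """

    chromosome: str
    segments: list[tuple[int, int, float]]
    hotspots: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self):
        prev_end = 0
        for s, e, r in self.segments:
            if s != prev_end or e <= s or r < 0:
                raise ValueError("segments must tile [0, length) with rho >= 0")
            prev_end = e

    @property
    def length(self) -> int:
        return self.segments[-1][1]

    def bp_weighted_mean(self) -> float:
        return sum(r * (e - s) for s, e, r in self.segments) / self.length

    def rho_at(self, positions) -> np.ndarray:
        pos = np.asarray(positions)
        starts = np.array([s for s, _, _ in self.segments])
        rhos = np.array([r for _, _, r in self.segments])
        idx = np.clip(np.searchsorted(starts, pos, side="right") - 1, 0, len(starts) - 1)
        return rhos[idx]

    def rate_map(self) -> msprime.RateMap:
        position = [s for s, _, _ in self.segments] + [self.length]
        rate = [r for _, _, r in self.segments]
        return msprime.RateMap(position=position, rate=rate)

    def to_landscape(self):
        from .landscape import RhoLandscape

        return RhoLandscape.from_intervals(self.chromosome, self.segments)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chromosome\tstart\tend\trho\tis_hotspot\tfold\n")
            hot = {(s, e): f for s, e, f in self.hotspots}
            for s, e, r in self.segments:
                f = hot.get((s, e))
                fh.write(f"{self.chromosome}\t{s}\t{e}\t{r:.10g}\t"
                         f"{int(f is not None)}\t{f if f is not None else 1}\n")

    @classmethod
    def from_tsv(cls, path) -> "TruthRecMap":
        df = pd.read_csv(path, sep="\t")
        segments = [(int(r.start), int(r.end), float(r.rho)) for r in df.itertuples()]
        hotspots = [(int(r.start), int(r.end), float(r.fold))
                    for r in df.itertuples() if r.is_hotspot]
        return cls(str(df["chromosome"].iloc[0]), segments, hotspots)


def _spawn_rngs(seed, k: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(k)]


def _msprime_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def build_truth_map(config: SimConfig, min_separation: int = 100_000) -> TruthRecMap:
    """Place the configured hotspots at random along the sequence.

    Placement is uniform at random subject to a minimum gap of
    ``min_separation`` bp between hotspots, mirroring a power-analysis
    design in which the fold of each planted hotspot is defined against
    genuinely background flanking sequence (the detection flank is 100 kb
    per side). The gap shrinks automatically when the sequence is too short
    to honour it; placement fails only when the hotspots themselves do not
    fit. Uses the classic spacings construction (uniform positions in the
    unoccupied length, offset by cumulative hotspot lengths plus gaps),
    exactly uniform over admissible placements. Hotspot order is shuffled
    so fold classes are not spatially ordered.
    """
    rng = _spawn_rngs(config.seed, 1)[0]
    spec = list(config.hotspot_spec)
    total_hs = sum(length for length, _ in spec)
    L = config.seq_length
    if spec and total_hs >= L:
        raise InfeasiblePlacementError(
            f"hotspots total {total_hs} bp but sequence is only {L} bp")
    if not spec:
        return TruthRecMap(config.chromosome,
                           [(0, L, config.background_rho)], [])
    k = len(spec)
    sep = min(min_separation, max(0, (L - total_hs - 1) // max(k - 1, 1)))
    order = rng.permutation(k)
    lengths = np.array([spec[i][0] for i in order])
    folds = np.array([spec[i][1] for i in order])
    free = L - total_hs - sep * (k - 1)
    u = np.sort(rng.uniform(0, free, size=k))
    offsets = np.concatenate([[0], np.cumsum(lengths[:-1] + sep)])
    starts = np.floor(u).astype(int) + offsets
    segments, hotspots = [], []
    cursor = 0
    for s, length, fold in zip(starts, lengths, folds):
        e = s + int(length)
        if s > cursor:
            segments.append((int(cursor), int(s), config.background_rho))
        segments.append((int(s), int(e), config.background_rho * float(fold)))
        hotspots.append((int(s), int(e), float(fold)))
        cursor = e
    if cursor < L:
        segments.append((int(cursor), int(L), config.background_rho))
    return TruthRecMap(config.chromosome, segments, hotspots)


def simulate_haplotypes(config: SimConfig, rec_map: TruthRecMap | None = None,
                        mutation_matrix: MutationMatrix | None = None,
                        out_vcf=None, gq: int = 99) -> HaplotypeBlock:
    """Coalescent-with-recombination sample of n haploid genomes.

    Segregating sites are painted after the fact: the ancestral base is
    drawn uniformly from {A,C,G,T} and the derived base from that base's
    row of the mutation matrix with the diagonal mass renormalized away.
    The same seed yields a byte-identical VCF.
    """
    if rec_map is None:
        rec_map = build_truth_map(config)
    if mutation_matrix is None:
        mutation_matrix = load_printed_matrix()
    rng_anc, rng_mut, rng_paint = _spawn_rngs(config.seed, 3)[:3]

    ts = msprime.sim_ancestry(
        samples=config.n_samples,
        ploidy=1,
        population_size=0.5,
        recombination_rate=rec_map.rate_map(),
        random_seed=_msprime_seed(rng_anc),
    )
    mts = msprime.sim_mutations(
        ts, rate=config.theta,
        model=msprime.BinaryMutationModel(),
        random_seed=_msprime_seed(rng_mut),
    )
    G = mts.genotype_matrix()  # (sites, samples), allele indices
    positions = np.array([int(s.position) for s in mts.sites()])
    derived_count = (G == 1).sum(axis=1)
    seg = (derived_count > 0) & (derived_count < config.n_samples)
    G = (G[seg] == 1).astype(np.int8)
    positions = positions[seg]

    S = len(positions)
    anc_idx = rng_paint.integers(0, 4, size=S)
    rows = mutation_matrix.offdiagonal_rows()
    der_idx = np.empty(S, dtype=np.int64)
    for b in range(4):
        sel = anc_idx == b
        if not sel.any():
            continue
        row = rows[b]
        if np.any(np.isnan(row)):
            raise ValueError(f"row {BASES[b]} has no off-diagonal mass")
        cdf = np.cumsum(row)
        der_idx[sel] = np.searchsorted(cdf, rng_paint.random(sel.sum()) * cdf[-1])
    base_arr = np.array(list(BASES))
    block = HaplotypeBlock(
        chromosome=config.chromosome,
        positions=positions,
        genotypes=G.T,
        ref=base_arr[anc_idx],
        alt=base_arr[der_idx],
        sequence_length=config.seq_length,
        gq=np.full((config.n_samples, S), gq, dtype=np.int16),
    )
    if out_vcf is not None:
        block.write_vcf(out_vcf)
    return block


# ---------------------------------------------------------------------------
# annotation


@dataclass
class SyntheticAnnotation:
    """A generated gene-dense annotation with its realized layout."""

    chromosome: str
    genome_length: int
    genes: pd.DataFrame      # start, end, strand (0-based half-open)
    features: pd.DataFrame   # type, start, end, strand, gene_id

    @property
    def genic_fraction(self) -> float:
        return float((self.genes["end"] - self.genes["start"]).sum()) / self.genome_length

    def intergenic_tracts(self) -> pd.DataFrame:
        rows = []
        cursor = 0
        for g in self.genes.itertuples():
            if g.start > cursor:
                rows.append((cursor, g.start))
            cursor = g.end
        if cursor < self.genome_length:
            rows.append((cursor, self.genome_length))
        return pd.DataFrame(rows, columns=["start", "end"])

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.chromosome} 1 {self.genome_length}\n")
            for g in self.genes.itertuples():
                gid = f"gene{g.Index}"
                fh.write(_gff_row(self.chromosome, "gene", g.start, g.end, g.strand,
                                  f"ID={gid}"))
                fh.write(_gff_row(self.chromosome, "mRNA", g.start, g.end, g.strand,
                                  f"ID={gid}.t1;Parent={gid}"))
            feats = self.features.sort_values(["start", "type"])
            counters: dict[str, int] = {}
            for f in feats.itertuples():
                gid = f"gene{f.gene_id}.t1"
                counters[gid] = counters.get(gid, 0) + 1
                fh.write(_gff_row(self.chromosome, f.type, f.start, f.end, f.strand,
                                  f"ID={gid}.{counters[gid]};Parent={gid}"))


def _gff_row(chrom, ftype, start, end, strand, attrs) -> str:
    # GFF3 is 1-based inclusive
    return f"{chrom}\trhoscape\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"


def _gene_features(start: int, end: int, strand: str, gene_id: int,
                   rng: np.random.Generator) -> list[tuple]:
    """Split a gene body into UTR5/CDS/intron/UTR3 children (intron implied
    as the unannotated genic remainder)."""
    length = end - start
    rows = []
    if length < 60:
        rows.append(("CDS", start, end, strand, gene_id))
        return rows
    utr5 = max(1, int(round(0.10 * length)))
    utr3 = max(1, int(round(0.10 * length)))
    body = length - utr5 - utr3
    n_introns = min(int(body // 1500), 8)
    if n_introns == 0:
        cds_blocks = [(0, body)]
    else:
        intron_total = int(0.35 * body)
        intron_len = max(1, intron_total // n_introns)
        exon_total = body - intron_len * n_introns
        n_exons = n_introns + 1
        cuts = np.linspace(0, exon_total, n_exons + 1).astype(int)
        cds_blocks = []
        offset = 0
        for i in range(n_exons):
            blk = (offset + cuts[i] + i * intron_len, offset + cuts[i + 1] + i * intron_len)
            cds_blocks.append(blk)
    if strand == "+":
        b0 = start + utr5
        rows.append(("five_prime_UTR", start, b0, strand, gene_id))
        for lo, hi in cds_blocks:
            if hi > lo:
                rows.append(("CDS", b0 + lo, b0 + hi, strand, gene_id))
        rows.append(("three_prime_UTR", end - utr3, end, strand, gene_id))
    else:
        b0 = start + utr3
        rows.append(("three_prime_UTR", start, b0, strand, gene_id))
        for lo, hi in cds_blocks:
            if hi > lo:
                rows.append(("CDS", b0 + lo, b0 + hi, strand, gene_id))
        rows.append(("five_prime_UTR", end - utr5, end, strand, gene_id))
    return rows


def generate_annotation(genome_length: int, genic_fraction: float = 0.858,
                        tract_median: float = 142.0, tract_log_sd: float = 1.972,
                        gene_log_sd: float = 0.6, n_genes: int | None = None,
                        seed: int | None = None, chromosome: str = "chr1",
                        out_gff=None) -> SyntheticAnnotation:
    """Generate a gene-dense annotation as alternating tract/gene layout.

    Intergenic tract lengths are lognormal with the given median and log-sd
    (defaults put ~50% of tracts under 142 bp and ~91% under 2 kb); gene
    lengths are lognormal with mean chosen so the expected genic fraction
    matches the request, then the whole layout is rescaled so the realized
    fraction lands within rounding error of it. ``n_genes`` forces a layout
    with exactly that many genes (``n_genes=1`` gives the degenerate
    two-tract case).
    """
    if not 0 < genic_fraction < 1:
        raise ValueError("genic_fraction must be in (0, 1)")
    rng = _spawn_rngs(seed, 1)[0]
    mu_t = np.log(tract_median)
    mean_tract = float(np.exp(mu_t + tract_log_sd ** 2 / 2))
    mean_gene = mean_tract * genic_fraction / (1 - genic_fraction)
    mu_g = np.log(mean_gene) - gene_log_sd ** 2 / 2

    if n_genes is None:
        est = max(1, int(np.ceil(genome_length / (mean_tract + mean_gene))) + 3)
        tracts = rng.lognormal(mu_t, tract_log_sd, size=est + 1)
        genes = rng.lognormal(mu_g, gene_log_sd, size=est)
        # walk the alternating layout until it covers the genome
        m = 1
        total = tracts[0]
        while m <= est:
            total += genes[m - 1] + tracts[m]
            if total >= genome_length:
                break
            m += 1
        m = min(m, est)
        tracts, genes = tracts[:m + 1], genes[:m]
    else:
        tracts = rng.lognormal(mu_t, tract_log_sd, size=n_genes + 1)
        genes = rng.lognormal(mu_g, gene_log_sd, size=n_genes)

    # rescale gene lengths for the exact requested fraction, then rescale
    # the whole layout to fit the genome exactly
    genes *= (genic_fraction / (1 - genic_fraction)) * tracts.sum() / genes.sum()
    scale = genome_length / (tracts.sum() + genes.sum())
    tracts *= scale
    genes *= scale

    lengths = np.empty(len(tracts) + len(genes))
    lengths[0::2] = tracts
    lengths[1::2] = genes
    bounds = np.round(np.concatenate([[0.0], np.cumsum(lengths)])).astype(int)
    bounds[-1] = genome_length

    gene_rows, feat_rows = [], []
    for i in range(len(genes)):
        s, e = int(bounds[2 * i + 1]), int(bounds[2 * i + 2])
        if e <= s:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((s, e, strand))
        feat_rows.extend(_gene_features(s, e, strand, len(gene_rows) - 1, rng))
    ann = SyntheticAnnotation(
        chromosome=chromosome,
        genome_length=genome_length,
        genes=pd.DataFrame(gene_rows, columns=["start", "end", "strand"]),
        features=pd.DataFrame(feat_rows,
                              columns=["type", "start", "end", "strand", "gene_id"]),
    )
    if out_gff is not None:
        ann.write_gff3(out_gff)
    return ann


# ---------------------------------------------------------------------------
# crossovers and MA mutations


def generate_crossovers(rec_map: TruthRecMap, n_offspring: int = 108,
                        r_scale: float = 12.0, interval_width: int = 1000,
                        seed: int | None = None):
    """Map-proportional crossovers for a set of meiotic offspring.

    Per offspring the crossover count is Poisson with mean
    ``r_scale`` (cM/Mb) × 10⁻⁸ × genome length — i.e. ``r_scale`` is the
    genome-average physical rate — and positions are sampled with density
    proportional to local ρ. Each crossover is reported as an interval of
    ``interval_width`` bp centred on the sampled breakpoint, mimicking
    marker-bounded resolution in tetrad data.
    """
    from .codiv import CrossoverTable

    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    rng = _spawn_rngs(seed, 1)[0]
    L = rec_map.length
    lam = r_scale * 1e-8 * L
    seg = np.array([(s, e, r) for s, e, r in rec_map.segments])
    weights = seg[:, 2] * (seg[:, 1] - seg[:, 0])
    if weights.sum() <= 0:
        weights = seg[:, 1] - seg[:, 0]
    weights = weights / weights.sum()
    rows = []
    counts = rng.poisson(lam, size=n_offspring)
    for off, k in enumerate(counts):
        if k == 0:
            continue
        seg_idx = rng.choice(len(seg), size=k, p=weights)
        for j in seg_idx:
            pos = int(rng.integers(seg[j, 0], seg[j, 1]))
            half = interval_width // 2
            rows.append((rec_map.chromosome,
                         max(0, pos - half), min(L, pos + half),
                         f"offspring_{off}"))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "offspring_id"])
    return CrossoverTable(df, n_individuals=n_offspring)


def generate_ma_mutations(matrix: MutationMatrix, n_mutations: int,
                          seed: int | None = None) -> list[tuple[str, str]]:
    """Sample (ancestral, derived) single-nucleotide mutations from a
    transition matrix with the diagonal renormalized away; ancestral bases
    are uniform over A,C,G,T."""
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    rng = _spawn_rngs(seed, 1)[0]
    rows = matrix.offdiagonal_rows()
    anc = rng.integers(0, 4, size=n_mutations)
    der = np.empty(n_mutations, dtype=np.int64)
    for b in range(4):
        sel = anc == b
        if not sel.any():
            continue
        row = rows[b]
        if np.any(np.isnan(row)):
            raise ValueError(f"row {BASES[b]} has no off-diagonal mass")
        cdf = np.cumsum(row)
        der[sel] = np.searchsorted(cdf, rng.random(sel.sum()) * cdf[-1])
    return [(BASES[a], BASES[d]) for a, d in zip(anc, der)]


def generate_genome_sequence(length: int, gc: float = 0.64,
                             seed: int | None = None,
                             gc_profile: tuple[int, np.ndarray] | None = None) -> str:
    """Random genome sequence with controlled GC content.

    ``gc_profile=(window, values)`` paints per-window GC fractions instead
    of a flat genome-wide value (used to construct known GC–ρ relations).
    """
    rng = _spawn_rngs(seed, 1)[0]
    if gc_profile is None:
        gc_arr = np.full(1, gc)
        window = length
    else:
        window, gc_arr = gc_profile
        gc_arr = np.asarray(gc_arr, dtype=float)
    out = []
    base_arr = np.array(list("ATGC"))
    for w, g in enumerate(gc_arr):
        n = min(window, length - w * window)
        if n <= 0:
            break
        p = np.array([(1 - g) / 2, (1 - g) / 2, g / 2, g / 2])
        out.append("".join(base_arr[rng.choice(4, size=n, p=p)]))
    return "".join(out)
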