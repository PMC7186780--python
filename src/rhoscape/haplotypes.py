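"""Haploid haplotype matrices and VCF round-tripping.

The central container is :class:`HaplotypeBlock`, an ``n_samples x n_sites``
matrix of 0/1 haploid calls (−1 for missing) with 0-based physical positions.
VCF emission follows VCF v4.2 with haploid ``GT`` and per-sample ``GQ``;
positions are converted to 1-based on write and back on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=rhoscape
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
"""


@dataclass
class HaplotypeBlock:
    """Biallelic haploid genotypes at segregating sites.

    Attributes
    ----------
    chromosome : str
        Chromosome label.
    positions : ndarray of int
        0-based site positions, strictly increasing.
    genotypes : ndarray of int8, shape (n_samples, n_sites)
        0 = ancestral/REF allele, 1 = derived/ALT allele, −1 = missing.
    ref, alt : ndarray of single-character strings
        REF (ancestral) and ALT (derived) bases per site.
    gq : ndarray of int16, shape (n_samples, n_sites), optional
        Phred-scaled genotype qualities; defaults to a constant 99.
    sequence_length : int
        Length in bp of the region the block was sampled from.
    """

    chromosome: str
    positions: np.ndarray
    genotypes: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    sequence_length: int
    gq: np.ndarray | None = None
    sample_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        if self.genotypes.shape[1] != self.positions.size:
            raise ValueError("positions/genotypes shape mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not self.sample_names:
            self.sample_names = [f"sample_{i}" for i in range(self.n_samples)]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def gq_matrix(self) -> np.ndarray:
        if self.gq is None:
            return np.full(self.genotypes.shape, 99, dtype=np.int16)
        return self.gq

    # ------------------------------------------------------------------
    # summaries

    def derived_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (derived allele count, called sample count)."""
        called = self.genotypes >= 0
        c = np.where(called, self.genotypes, 0).sum(axis=0)
        k = called.sum(axis=0)
        return c, k

    def pairwise_diversity(self, per_bp: bool = True) -> float:
        """Mean pairwise difference π, per bp of ``sequence_length``.

        π per site = c(k−c)/C(k,2) with c the derived count among k called
        haplotypes; sites with <2 calls contribute zero.
        """
        c, k = self.derived_counts()
        ok = k >= 2
        c, k = c[ok].astype(float), k[ok].astype(float)
        per_site = c * (k - c) / (k * (k - 1) / 2.0)
        total = float(per_site.sum())
        return total / self.sequence_length if per_bp else total

    def minor_allele_frequencies(self) -> np.ndarray:
        """MAF over called haploid alleles; NaN where nothing is called."""
        c, k = self.derived_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(k > 0, c / np.maximum(k, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def filter_maf(self, maf_min: float = 0.1) -> "HaplotypeBlock":
        """Sites with MAF strictly above ``maf_min`` (singleton exclusion)."""
        keep = self.minor_allele_frequencies() > maf_min
        keep &= ~np.isnan(self.minor_allele_frequencies())
        return self.subset(np.flatnonzero(keep))

    def subset(self, site_idx: np.ndarray) -> "HaplotypeBlock":
        return HaplotypeBlock(
            chromosome=self.chromosome,
            positions=self.positions[site_idx],
            genotypes=self.genotypes[:, site_idx],
            ref=self.ref[site_idx],
            alt=self.alt[site_idx],
            sequence_length=self.sequence_length,
            gq=None if self.gq is None else self.gq[:, site_idx],
            sample_names=list(self.sample_names),
        )

    # ------------------------------------------------------------------
    # VCF I/O

    def write_vcf(self, path) -> None:
        """Emit a haploid VCF v4.2 (1-based positions, GT:GQ per sample)."""
        gq = self.gq_matrix()
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER.format(chrom=self.chromosome, length=self.sequence_length))
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.sample_names) + "\n")
            for j in range(self.n_sites):
                calls = []
                for i in range(self.n_samples):
                    g = self.genotypes[i, j]
                    gt = "." if g < 0 else str(int(g))
                    calls.append(f"{gt}:{int(gq[i, j])}")
                fh.write(
                    f"{self.chromosome}\t{self.positions[j] + 1}\t.\t{self.ref[j]}\t"
                    f"{self.alt[j]}\t.\tPASS\t.\tGT:GQ\t" + "\t".join(calls) + "\n"
                )

    @classmethod
    def read_vcf(cls, path) -> "HaplotypeBlock":
        """Read a haploid biallelic VCF produced by this package (or alike)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=False)
        samples = list(vcf.samples)
        length = 0
        for line in vcf.raw_header.splitlines():
            if line.startswith("##contig"):
                for part in line.strip("<>").split(","):
                    if part.startswith("length="):
                        length = int(part.split("=")[1].rstrip(">"))
        chrom = None
        positions, gts, gqs, refs, alts = [], [], [], [], []
        for v in vcf:
            if len(v.ALT) != 1:
                continue
            chrom = v.CHROM
            positions.append(v.POS - 1)
            refs.append(v.REF)
            alts.append(v.ALT[0])
            # haploid GT: first allele of each genotype triplet
            g = np.array([row[0] for row in v.genotypes], dtype=np.int8)
            gts.append(g)
            q = v.format("GQ")
            gqs.append(
                np.full(len(samples), 99, dtype=np.int16)
                if q is None
                else q.reshape(-1).astype(np.int16)
            )
        vcf.close()
        if not positions:
            raise ValueError(f"no biallelic sites in {path}")
        positions = np.array(positions)
        return cls(
            chromosome=chrom,
            positions=positions,
            genotypes=np.array(gts).T,
            ref=np.array(refs),
            alt=np.array(alts),
            sequence_length=length or int(positions[-1] + 1),
            gq=np.array(gqs, dtype=np.int16).T,
            sample_names=samples,
        )


def inject_low_gq(block: HaplotypeBlock, n_sites: int, gq_value: int = 10,
                  seed: int | None = None) -> tuple[HaplotypeBlock, np.ndarray]:
    """Set all-sample GQ to ``gq_value`` at ``n_sites`` random sites.

    Returns the modified block (copy) and the affected site indices; used to
    exercise quality-based site filters on synthetic data.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(block.n_sites, size=min(n_sites, block.n_sites), replace=False)
    gq = block.gq_matrix().copy()
    gq[:, idx] = gq_value
    out = HaplotypeBlock(
        chromosome=block.chromosome,
        positions=block.positions.copy(),
        genotypes=block.genotypes.copy(),
        ref=block.ref.copy(),
        alt=block.alt.copy(),
        sequence_length=block.sequence_length,
        gq=gq,
        sample_names=list(block.sample_names),
    )
    return out, np.sort(idx)
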