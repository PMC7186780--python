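"""SNP retention filters for haploid multi-sample VCFs.

Sites are kept for recombination-rate estimation when they pass all of:

1. mean genotype quality across called samples strictly above a threshold
   (default 30);
2. exactly one alternate allele (diallelic SNP);
3. minor allele frequency among called haploid alleles strictly above a
   threshold (default 0.1, which excludes singletons in a sample of 19).

Sites with no called samples are excluded and counted separately. The
filter reports how many sites each rule rejected; a site failing several
rules increments every corresponding counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotypes import HaplotypeBlock


@dataclass
class FilterCounts:
    """Per-rule rejection tallies plus input/retained totals."""

    n_input: int = 0
    n_retained: int = 0
    no_calls: int = 0
    low_gq: int = 0
    multiallelic: int = 0
    low_maf: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SiteDecision:
    keep: bool
    failed: list[str] = field(default_factory=list)


def site_passes(gqs, alleles, n_alt: int, gq_min: float = 30.0,
                maf_min: float = 0.1) -> SiteDecision:
    """Evaluate one site.

    ``gqs``: per-sample GQ for called samples only (missing dropped by the
    caller); ``alleles``: called haploid allele indices (0 = REF, >0 = ALT);
    ``n_alt``: number of ALT alleles at the site.
    """
    alleles = np.asarray(alleles)
    gqs = np.asarray(gqs, dtype=float)
    failed = []
    if alleles.size == 0:
        return SiteDecision(False, ["no_calls"])
    if not (gqs.size and gqs.mean() > gq_min):
        failed.append("low_gq")
    if n_alt != 1:
        failed.append("multiallelic")
    else:
        p = float(np.mean(alleles > 0))
        if not (min(p, 1 - p) > maf_min):
            failed.append("low_maf")
    return SiteDecision(not failed, failed)


def filter_vcf(path_in, path_out=None, gq_min: float = 30.0,
               maf_min: float = 0.1) -> FilterCounts:
    """Stream a VCF through the site filters, optionally writing survivors.

    Returns per-rule rejection counts. The filter is idempotent: running it
    on its own output changes nothing.
    """
    from cyvcf2 import VCF, Writer

    vcf = VCF(str(path_in), gts012=False)
    writer = Writer(str(path_out), vcf) if path_out is not None else None
    counts = FilterCounts()
    for v in vcf:
        counts.n_input += 1
        g = np.array([row[0] for row in v.genotypes], dtype=np.int16)
        called = g >= 0
        q = v.format("GQ")
        if q is None:
            gqs = np.full(int(called.sum()), 99.0)
        else:
            gqs = q.reshape(-1).astype(float)[called]
        decision = site_passes(gqs, g[called], n_alt=len(v.ALT),
                               gq_min=gq_min, maf_min=maf_min)
        for rule in decision.failed:
            setattr(counts, rule, getattr(counts, rule) + 1)
        if decision.keep:
            counts.n_retained += 1
            if writer is not None:
                writer.write_record(v)
    if writer is not None:
        writer.close()
    vcf.close()
    return counts


def filter_block(block: HaplotypeBlock, gq_min: float = 30.0,
                 maf_min: float = 0.1) -> tuple[HaplotypeBlock, FilterCounts]:
    """Apply the same retention rules to an in-memory haplotype block.

    The block is already biallelic by construction, so the multiallelic rule
    never fires here; it exists for VCF input.
    """
    counts = FilterCounts(n_input=block.n_sites)
    gq = block.gq_matrix()
    called = block.genotypes >= 0
    n_called = called.sum(axis=0)
    keep = np.ones(block.n_sites, dtype=bool)

    no_calls = n_called == 0
    counts.no_calls = int(no_calls.sum())
    keep &= ~no_calls

    with np.errstate(invalid="ignore"):
        mean_gq = np.where(n_called > 0,
                           np.where(called, gq, 0).sum(axis=0) / np.maximum(n_called, 1),
                           np.nan)
    low_gq = (n_called > 0) & ~(mean_gq > gq_min)
    counts.low_gq = int(low_gq.sum())
    keep &= ~low_gq

    maf = block.minor_allele_frequencies()
    low_maf = (n_called > 0) & ~(maf > maf_min)
    counts.low_maf = int(low_maf.sum())
    keep &= ~low_maf

    counts.n_retained = int(keep.sum())
    return block.subset(np.flatnonzero(keep)), counts
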