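# rhoscape

Fine-scale recombination-rate landscapes, hotspot detection, and the
frequency of sex, estimated from haploid population genomic data — with a
coalescent simulation layer that generates every input under known ground
truth.

`rhoscape` is aimed at population geneticists working on facultatively
sexual microbes (the motivating system is a unicellular green alga sampled
as 19 natural haploid strains). In such organisms the population
recombination rate ρ = 2Nₑr reflects not just the per-meiosis crossover
rate r but also how often sex happens at all, which makes LD-based
recombination maps the entry point to three questions this package covers
end to end:

1. **What does the recombination landscape look like?** Pairwise r² between
   SNPs, the Hill–Weir decay expectation

   E(r²) = (10+Γ)/(22+13Γ+Γ²) · [1 + (3+Γ)(12+12Γ+Γ²)/(n(22+13Γ+Γ²))],
   Γ = ρ·d,

   fitted by nonlinear least squares for chromosome-scale ρ̂ and decay
   statistics (half-decay distance, baseline), plus a windowed ρ estimator
   that yields a landscape in non-overlapping 2-kb windows by jointly
   inverting simulation-calibrated response surfaces for r² and the
   four-gamete-violation rate (see `docs/methods.md`). Hotspots are runs of
   windows ≥2 kb long with mean ρ ≥5× the surrounding 200 kb.
2. **What predicts it?** Per-bp annotation classification from GFF3
   (CDS/intron/UTR/intergenic, intergenic tract lengths, gene-proximal
   zones), mean ρ per category with bootstrap CIs, ρ ~ annotation ×
   SNP-density regression, GC–ρ rank correlation, hotspot–annotation
   enrichment (Fisher's exact test), and crossover rates (cM/Mb) binned by
   ρ or by silent-site diversity θπ.
3. **How often is sex?** With lab rates r (cM/Mb) and μ (per bp per
   generation): f = (ρ/r)/(θ/μ) meioses per mitosis, the realized
   per-generation rate ρ/2Nₑ, and calendar conversions.

Because the real study data (deep short-read sequencing of 19 strains) is
not needed to validate the machinery, the `simulate` module generates all
inputs from scratch — haploid coalescent samples under piecewise-constant
recombination maps with planted hotspots, VCFs with genotype qualities,
gene-dense GFF3 annotations, crossover tables from meiotic offspring, and
mutation-accumulation style mutation lists — keeping the ground truth for
power and recovery analysis.

## Worked example

```python
from rhoscape import SexFrequencyInputs, frequency_of_sex, realized_r, generations_to_days

inputs = SexFrequencyInputs(rho=4.09e-3, theta=2.75e-2, r_cm_mb=12.0,
                            mu=9.63e-10, ne=1.4e7)
f, gens = frequency_of_sex(inputs)
print(f"{f:.6f}", round(gens), realized_r(inputs.rho, inputs.ne),
      generations_to_days(gens))
```

prints

```
0.001194 838 0.014607142857142855 335.1385112233317
```

i.e. roughly one meiosis per ~840 mitotic generations (about 335 days at
2.5 doublings per day — a seasonal sexual cycle), and a realized
per-generation crossover rate of ~0.015 cM/Mb, three orders of magnitude
below the lab-cross rate because most generations are clonal.

A full synthetic analysis — simulate, filter (mean GQ > 30, biallelic,
MAF > 0.1), windowed ρ, hotspot detection with power against the planted
truth, annotation correlates, crossover binning, frequency of sex — runs
with one command and is byte-reproducible per seed:

```bash
rhoscape demo --seed 7 --out demo_report/
```

Narrative single-topic scripts live in `examples/`.

## Layout

| module | contents |
| --- | --- |
| `rhoscape.simulate` | coalescent haplotypes, truth maps, annotations, crossovers, MA mutations |
| `rhoscape.haplotypes` | `HaplotypeBlock`, VCF I/O, diversity, MAF filtering |
| `rhoscape.filters` | SNP retention rules (GQ / biallelic / MAF) |
| `rhoscape.mutmat` | 4×4 mutation transition matrices |
| `rhoscape.ld` | r², decay expectation + fits, calibrated windowed ρ estimator |
| `rhoscape.landscape` | interval landscapes, window summaries, chromosome stats |
| `rhoscape.hotspots` | detection, power vs truth, enrichment |
| `rhoscape.correlates` | annotation masks, bootstrap CIs, regressions, GC |
| `rhoscape.codiv` | crossover rates by ρ bin and diversity bin |
| `rhoscape.sexfreq` | frequency of sex, realized r |
| `rhoscape.pipeline` / `rhoscape.cli` | end-to-end demo and `rhoscape` command |
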