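# Methods

## Model and scope

The package analyses haploid population samples in which linkage
disequilibrium (LD) carries the signal of historical recombination. The
population recombination rate is parameterized as ρ = 2Nₑr per bp (haploid
convention throughout; the two-locus sampling literature also uses 4Nₑr for
diploids). Diversity is θ = 2Nₑμ per bp, estimated by θπ, the mean pairwise
difference per site. In a facultatively sexual organism r itself is the
product of the per-meiosis crossover rate and the frequency of sex f, which
is what makes the closed-form estimator f = (ρ/r_lab)/(θ/μ) possible: the
mutation clock runs every generation, the recombination clock only in
sexual ones.

## Coalescent simulation layer

Haplotypes are generated with `msprime` under a piecewise-constant
recombination map. The simulation uses ploidy 1 with population size fixed
at 1/2, so the per-bp mutation rate passed to the simulator *is* θ and the
per-bp recombination rate *is* ρ; no rescaling is needed downstream.
Mutations use a binary (0/1) model on a discrete genome; segregating sites
are then painted: the ancestral base is uniform over {A,C,G,T} (the data
this emulates provide no outgroup, so no empirical ancestral base
composition is assumed) and the derived base is drawn from the ancestral
base's row of the 4×4 mutation matrix with the diagonal renormalized away.
Multiple mutations at one site are collapsed to the biallelic 0/1 states and
non-segregating sites dropped.

Defaults are the study conditions: n = 19 haploid samples, θ = 0.03/bp,
1 Mb chromosomes, background ρ = 0.001/bp, and eight 2-kb hotspots (two
each at 10×, 20×, 40×, 60× background). Hotspot placement is uniform at
random subject to a 100-kb minimum separation. The separation matches the
hotspot detector's flank scale: a planted hotspot's fold is defined against
its surrounding 200 kb, so the power analysis is only well-posed when that
flanking sequence is genuinely background. Without the constraint,
neighbouring hotspots fall inside each other's flanks often enough that
even a noise-free detector caps at ~0.88 power, with evenly grid-split 10×
hotspots (5.5× per window) pushed below the 5-fold criterion by inflated
flank means.

The annotation generator lays out alternating intergenic tracts and genes.
Tract lengths are lognormal with median 142 bp and log-sd 1.972 — chosen so
half of tracts are under 142 bp and ~91% under 2 kb, the tract-length
profile of a gene-dense genome — and gene lengths are lognormal with the
mean set so the expected genic fraction matches the request (default
85.8%); the realized layout is rescaled to hit the genome length and the
fraction to within rounding. Genes receive UTR5/CDS/intron/UTR3 children
(introns implied by the unannotated genic remainder, as in real GFF3).

Crossovers for `n_offspring` meiotic products are Poisson per offspring
with mean r_scale × 10⁻⁸ × L (r_scale in cM/Mb is the genome-average
physical rate; default 12 cM/Mb, 108 offspring) and positions sampled with
density proportional to local ρ, reported as ±500 bp intervals to mimic
marker-bounded resolution.

What the generator deliberately does *not* emulate: population structure
and demography (a single panmictic coalescent), selection, gene conversion,
indels, sequencing/alignment error (genotype qualities default to a
constant 99, with an injection helper for filter tests), and GC-biased
substitution. Passing tests therefore validate the estimators under
neutral, equilibrium, error-free conditions; on real data, structure and
selection bias ρ̂ (usually downward through diversity reduction) in ways the
suite does not measure.

## Site filters

Retention requires all of: mean genotype quality over called samples
strictly above 30, exactly one alternate allele, and minor allele frequency
strictly above 0.1 computed over called haploid alleles only (singletons in
19 samples fail: 1/19 ≈ 0.053). Sites with zero called samples are counted
separately. Counters increment for every rule a site fails, so injected
single-rule violations reconcile exactly.

## LD and the windowed ρ estimator

r² is D²/(p(1−p)q(1−q)) on haploid 0/1 calls with pairwise-complete
missing handling and no lower r² cutoff. Chromosome-scale ρ̂ comes from
bounded least squares of the Hill–Weir sampling expectation against raw
(d, r²) pairs (ρ ∈ [0, 10], start 0.001; a distance-binned variant is
available). Decay statistics take the fitted curve's value at d = 1 bp as
the starting value; the half-decay distance is the smallest integer d at
which the curve falls to half that (bisection — the curve is monotone), and
the baseline is the smallest d where the central-difference slope magnitude
drops below 0.5×10⁻⁵ per bp, i.e. where the instantaneous change rounds to
zero at five decimal digits.

The windowed estimator produces a landscape in non-overlapping windows
(default 2 kb) and is deliberately more elaborate than a per-window curve
fit, for three measured reasons.

First, under a MAF filter the closed-form expectation is biased
compressively (fits at background ρ = 0.001 land ~40% high; at hotspot
rates ~15–20% low). The estimator therefore inverts **empirical response
surfaces** tabulated from coalescent simulations at a ladder of uniform ρ
values under the same study conditions (n, θ, MAF filter), made monotone
in ρ by pooled-adjacent-violators and interpolated on a log-ρ grid
(`calibrate_r2`; high-ρ ladder sims use proportionally shorter sequences
since coalescent cost grows with ρ×L).

Second, two responses are fitted jointly per pair: the mean of r², and the
**four-gamete-violation indicator** (all four haplotypes 00/01/10/11
observed — evidence of at least one historical crossover between the
sites). The FGV rate matters because r² saturates at its ~1/n sampling
floor once Γ ≳ 30, leaving rates above ~10× background barely
distinguishable by moments alone, while the FGV rate keeps rising
(measured under the default conditions at d = 500–1000 bp: 0.08 at
ρ = 0.001, 0.35 at 0.01, 0.42 at 0.02). Both responses enter one
inverse-variance weighted least squares (Bernoulli variance for FGV).

Third, a pair's scaled length is Γ = Σ_w ρ_w × overlap(pair, w), so pairs
spanning window boundaries carry information about every window they
cross; treating each window in isolation both attenuates hotspots and
blurs them into neighbours. Window rates are estimated jointly:
per-window stratified pair samples (short spans ≤2 kb and longer spans
≤10 kb capped separately, so the local decay signal is not swamped by the
more numerous long pairs) and coordinate-descent minimization with
alternating sweep direction (Gauss–Seidel smearing is directional).
Optimization per window is a log-grid scan with two zoom rounds — plain
bounded Brent fails on the flat SSE plateaus created by clamping ρ to the
calibrated range.

Per-window ρ̂ retains some right skew (genealogical noise is irreducible
at the 2-kb scale), so its mean can overshoot the truth even when the
median is calibrated, and any flank *mean* computed from the landscape
inherits that bias. `calibrate_window_bias` runs the full estimator on
simulated study-condition landscapes (hotspots included, since their
shoulders leak a little rate into nearby background windows) and solves
for the additive offset δ such that over true-background windows
mean(max(ρ̂ − δ, 0)) equals the background rate; with the joint r²+FGV fit
the required offset is small (~10⁻⁴ or less). Windows with fewer than 30
usable pairs, or whose fit runs into the ρ ceiling (LD at its sampling
floor; the rate is unidentifiable upward), are reported missing.

Measured on the default study conditions over twenty 1-Mb replicates, the
full stack (simulate → filter → calibrated windowed ρ → detector) recovers
~0.92 of planted hotspots overall (10×: ~0.75, 20×: ~0.95, 40×: ~0.98,
60×: 1.0); the residual misses are 10× hotspots split evenly across the
window grid — cases that sit within a few percent of the 5-fold criterion
even with error-free rates.

## Hotspot detection and power

A window is flagged when its mean ρ is at least `fold` (default 5×) times
the bp-weighted mean of windows within `flank` (default 100 kb) on each
side, focal window excluded, flanks truncated at chromosome ends, missing
windows ignored; windows with zero or undefined flank mean are skipped.
Adjacent flagged windows merge; merged regions shorter than 2 kb are
dropped. Power against a truth map counts a planted hotspot as detected on
any ≥1 bp overlap with a detected region. Enrichment uses Fisher's exact
test on a 2×2 table of bp counts (hotspot × annotation); a window-count
mode is available (window = hotspot on any overlap, annotated at ≥50% bp).

## Annotation correlates

GFF3 classification paints gene bodies as intron and overwrites with UTR
then CDS, giving the precedence CDS > UTR > intron > intergenic for
overlapping isoforms; unstranded features count as + strand. Intergenic
tracts are measured between merged gene bodies (chromosome ends included),
classed short (<2 kb) or long, with the 2 kb at each gene-abutting end
marked gene-proximal. Mean ρ per category resamples bp-level ρ values
(percentile bootstrap, default 1000 replicates; categories larger than
200k bp are subsampled for the resampling only). The ρ ~ annotation ×
SNP-density regression is OLS with treatment coding; constant density drops
the density terms with a flag, and standardized coefficients are reported
alongside raw ones. GC–ρ uses Spearman rank correlation on non-overlapping
windows with N bases excluded from the GC denominator.

## Crossover rates and diversity

cM/Mb per bin = (CO count / n individuals × 100) / (bin bp / 10⁶). COs are
assigned to ρ bins by the ρ at their interval midpoint (bins half-open,
values at or above the range top go to a flagged overflow bin excluded
from regressions; midpoints outside landscape coverage count as
unassigned). θπ windows use silent sites only — in synthetic mode the
intergenic + intronic positions of the generated annotation — and windows
with <500 silent sites are dropped. For diversity binning a CO takes the
mean θπ of retained windows overlapping its interval; bins aggregating
<200 kb (scaled proportionally for sub-Mb demo genomes) are discarded
before the OLS of rate on bin midpoint.

## Frequency of sex

f = (ρ/r)/(θ/μ) with r converted from cM/Mb at exactly 10⁻⁸ per bp per
cM/Mb. f > 1 (outside the approximation's domain) warns rather than
clamps. Realized per-generation rate: ρ/(2Nₑ), reported in cM/Mb;
generations convert to days by dividing by doublings per day (default 2.5).
No uncertainty is propagated — the estimator is a point-value combination
of four scalars, and the dominant errors (selection at linked sites
depressing ρ̂) are systematic, not sampling.

## Numerical and testing choices

- Problem sizes: the test suite simulates 1-Mb chromosomes for the power
  replication (twenty replicates) and 100-kb regions elsewhere; the
  estimator calibration uses a ten-point ρ ladder with three replicates
  each. These sizes give Monte-Carlo error comfortably inside the asserted
  bounds.
- Statistical assertions on stochastic quantities are seeded and use
  explicit sampling bounds (3 SE for means; joint Šidák-adjusted binomial
  bounds for the mutation-matrix recovery).
- Coordinates are 0-based half-open internally; VCF and GFF3 emission and
  parsing are 1-based per those standards; interval ρ files are 1-based
  half-open [left_snp, right_snp).
- All randomness flows from a single seed per entry point through
  `numpy.random.SeedSequence` spawning; fixed seeds give byte-identical
  VCF/GFF/TSV/JSON outputs (no timestamps in any emitted file).
- Known limitations: the windowed estimator's per-window variance is
  genealogy-limited, so single-window rates are order-of-magnitude
  estimates, not precise values; the calibration is tied to the study
  conditions it was simulated under (n, θ, MAF filter) and should be
  regenerated for other designs; Fisher's exact test on bp counts treats
  bp as independent, which real autocorrelated landscapes violate — the
  window-count mode is the conservative alternative.
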