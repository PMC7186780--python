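"""Annotation correlates of the recombination landscape.

Classifies every genome position as CDS, UTR, intron or intergenic from a
GFF3 annotation (precedence CDS > UTR > intron > intergenic for overlapping
isoforms), measures intergenic tracts and their gene-proximal ends, and
provides the statistical comparisons used on such masks: per-annotation
mean ρ with bootstrap CIs, ρ ~ annotation × SNP-density regression,
GC–ρ rank correlation, and Mann–Whitney contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .landscape import RhoLandscape

LABELS = ("intergenic", "CDS", "intron", "UTR5", "UTR3")
_LABEL_CODE = {name: i for i, name in enumerate(LABELS)}

#: distance from a gene edge that counts as gene-proximal intergenic sequence
PROXIMAL_BP = 2000
#: intergenic tract length separating the short/long tract classes
TRACT_LENGTH_SPLIT = 2000


class AnnotationError(ValueError):
    """Malformed annotation input (reported with the feature id)."""


@dataclass
class AnnotationMask:
    """Per-bp annotation labels plus intergenic tract structure.

    ``labels`` maps chromosome → int8 array over [0, length) with codes
    indexing :data:`LABELS`. ``tracts`` lists intergenic tracts with their
    length class; gene-proximal zones are the ``PROXIMAL_BP`` at each tract
    end abutting a gene.
    """

    labels: dict[str, np.ndarray]
    tracts: pd.DataFrame  # chromosome, start, end, length, length_class
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def genome_length(self, chromosome: str) -> int:
        return int(self.labels[chromosome].size)

    def label_array(self, chromosome: str) -> np.ndarray:
        return self.labels[chromosome]

    def label_mask(self, chromosome: str, label: str) -> np.ndarray:
        return self.labels[chromosome] == _LABEL_CODE[label]

    def bp_counts(self, chromosome: str | None = None) -> dict[str, int]:
        chroms = [chromosome] if chromosome else list(self.labels)
        out = {name: 0 for name in LABELS}
        for c in chroms:
            counts = np.bincount(self.labels[c], minlength=len(LABELS))
            for i, name in enumerate(LABELS):
                out[name] += int(counts[i])
        return out

    def genic_mask(self, chromosome: str) -> np.ndarray:
        return self.labels[chromosome] != _LABEL_CODE["intergenic"]

    def silent_mask(self, chromosome: str) -> np.ndarray:
        """Intergenic + intronic positions (silent-site proxy)."""
        lab = self.labels[chromosome]
        return (lab == _LABEL_CODE["intergenic"]) | (lab == _LABEL_CODE["intron"])

    def gene_proximal_mask(self, chromosome: str) -> np.ndarray:
        """Intergenic positions within ``PROXIMAL_BP`` of a gene edge."""
        L = self.genome_length(chromosome)
        out = np.zeros(L, dtype=bool)
        for t in self.tracts[self.tracts["chromosome"] == chromosome].itertuples():
            if t.gene_left:
                out[t.start:min(t.start + PROXIMAL_BP, t.end)] = True
            if t.gene_right:
                out[max(t.end - PROXIMAL_BP, t.start):t.end] = True
        return out & self.label_mask(chromosome, "intergenic")

    def tract_class_mask(self, chromosome: str, length_class: str) -> np.ndarray:
        L = self.genome_length(chromosome)
        out = np.zeros(L, dtype=bool)
        sel = self.tracts[(self.tracts["chromosome"] == chromosome)
                          & (self.tracts["length_class"] == length_class)]
        for t in sel.itertuples():
            out[t.start:t.end] = True
        return out & self.label_mask(chromosome, "intergenic")


def _parse_gff(gff_path):
    import gffutils

    try:
        db = gffutils.create_db(str(gff_path), ":memory:",
                                merge_strategy="create_unique", force=True,
                                keep_order=True)
    except Exception as exc:  # malformed file
        raise AnnotationError(f"cannot parse GFF3 {gff_path}: {exc}") from exc
    return db


def classify_sites(gff_path, genome_lengths: dict[str, int]) -> AnnotationMask:
    """Label every bp of the genome from a GFF3 annotation.

    Gene bodies default to intron; CDS and UTR children overwrite with the
    precedence CDS > UTR > intron. Intergenic tracts are measured between
    adjacent gene bodies (chromosome ends included) and classified as short
    (< 2 kb) or long; unstranded features are treated as + strand.
    """
    db = _parse_gff(gff_path)
    labels = {c: np.zeros(length, dtype=np.int8)
              for c, length in genome_lengths.items()}
    gene_rows = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in labels:
            raise AnnotationError(f"feature {gene.id}: unknown chromosome {gene.seqid}")
        if gene.end < gene.start:
            raise AnnotationError(f"feature {gene.id}: end < start")
        s, e = gene.start - 1, gene.end  # GFF3 is 1-based inclusive
        arr = labels[gene.seqid]
        if e > arr.size:
            raise AnnotationError(f"feature {gene.id}: beyond chromosome end")
        arr[s:e] = _LABEL_CODE["intron"]
        gene_rows.append((gene.seqid, s, e, gene.strand if gene.strand in "+-" else "+"))
    type_order = (("five_prime_UTR", "UTR5"), ("three_prime_UTR", "UTR3"), ("CDS", "CDS"))
    for ftype, label in type_order:
        for feat in db.features_of_type(ftype):
            arr = labels.get(feat.seqid)
            if arr is None:
                raise AnnotationError(f"feature {feat.id}: unknown chromosome {feat.seqid}")
            arr[feat.start - 1:feat.end] = _LABEL_CODE[label]

    genes = pd.DataFrame(gene_rows, columns=["chromosome", "start", "end", "strand"])
    tract_rows = []
    for chrom, length in genome_lengths.items():
        g = genes[genes["chromosome"] == chrom].sort_values("start")
        merged = []
        for row in g.itertuples():
            if merged and row.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], row.end)
            else:
                merged.append([row.start, row.end])
        cursor = 0
        bounds = merged + [[length, length]]
        for i, (gs, ge) in enumerate(bounds):
            if gs > cursor:
                tlen = gs - cursor
                tract_rows.append((
                    chrom, cursor, gs, tlen,
                    "short" if tlen < TRACT_LENGTH_SPLIT else "long",
                    cursor > 0,          # gene on the left
                    i < len(merged),     # gene on the right
                ))
            cursor = max(cursor, ge)
    tracts = pd.DataFrame(tract_rows, columns=[
        "chromosome", "start", "end", "length", "length_class",
        "gene_left", "gene_right"])
    return AnnotationMask(labels=labels, tracts=tracts, genes=genes)


# ---------------------------------------------------------------------------
# rho by annotation


def _bootstrap_ci(values: np.ndarray, n_boot: int, rng: np.random.Generator,
                  alpha: float = 0.05) -> tuple[float, float]:
    m = values.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = values[rng.integers(0, m, m)].mean()
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def annotation_rho(mask: AnnotationMask, landscape: RhoLandscape,
                   n_boot: int = 1000, seed: int | None = None,
                   categories: dict[str, np.ndarray] | None = None,
                   max_points: int | None = 200_000) -> pd.DataFrame:
    """Mean ρ per annotation category with bootstrap percentile 95% CIs.

    The unit of resampling is the bp-level ρ value. ``categories`` may
    supply extra boolean masks (per chromosome concatenated in chromosome
    order); by default the five primary labels plus intergenic tract
    classes and gene-proximal zones are reported. ``max_points`` caps the
    number of bp values bootstrapped per category (simple random subsample)
    to keep the resampling tractable on large genomes; the point estimate
    always uses every bp.
    """
    rng = np.random.default_rng(seed)
    chroms = [c for c in mask.labels if c in landscape.chromosomes]
    rho_per_bp = {c: landscape.per_bp(c)[:mask.genome_length(c)] for c in chroms}

    def collect(masks_by_chrom) -> np.ndarray:
        vals = [rho_per_bp[c][masks_by_chrom[c][:rho_per_bp[c].size]] for c in chroms]
        v = np.concatenate(vals) if vals else np.array([])
        return v[~np.isnan(v)]

    cats: dict[str, dict[str, np.ndarray]] = {}
    for label in LABELS:
        cats[label] = {c: mask.label_mask(c, label) for c in chroms}
    cats["genic"] = {c: mask.genic_mask(c) for c in chroms}
    cats["intergenic_short_tract"] = {c: mask.tract_class_mask(c, "short") for c in chroms}
    cats["intergenic_long_tract"] = {c: mask.tract_class_mask(c, "long") for c in chroms}
    cats["gene_proximal"] = {c: mask.gene_proximal_mask(c) for c in chroms}
    cats["nonflank"] = {
        c: mask.label_mask(c, "intergenic") & ~mask.gene_proximal_mask(c) for c in chroms}
    if categories:
        cats.update(categories)

    rows = []
    for name, masks in cats.items():
        v = collect(masks)
        if v.size == 0:
            rows.append((name, np.nan, np.nan, np.nan, 0))
            continue
        mean = float(v.mean())
        vb = v
        if max_points is not None and v.size > max_points:
            vb = v[rng.choice(v.size, max_points, replace=False)]
        lo, hi = _bootstrap_ci(vb, n_boot, rng)
        rows.append((name, mean, lo, hi, int(v.size)))
    return pd.DataFrame(rows, columns=["category", "mean_rho", "ci_low", "ci_high", "n_bp"])


def annotation_tracts(mask: AnnotationMask, landscape: RhoLandscape,
                      snp_positions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Contiguous same-label tracts with their mean ρ and SNP density."""
    rows = []
    for chrom in mask.labels:
        if chrom not in landscape.chromosomes:
            continue
        lab = mask.labels[chrom]
        rho = landscape.per_bp(chrom)[:lab.size]
        pos = np.asarray(snp_positions.get(chrom, np.array([], dtype=int)))
        breaks = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [lab.size]])
        for s, e in zip(starts, ends):
            seg = rho[s:e]
            seg = seg[~np.isnan(seg)]
            n_snp = int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
            rows.append((chrom, int(s), int(e), LABELS[lab[s]],
                         float(seg.mean()) if seg.size else np.nan,
                         n_snp / (e - s)))
    return pd.DataFrame(rows, columns=[
        "chromosome", "start", "end", "annotation", "rho", "snp_density"])


@dataclass
class RegressionResult:
    params: pd.Series
    pvalues: pd.Series
    r_squared: float
    dropped_interaction: bool
    standardized_params: pd.Series | None = None


def rho_density_regression(tracts: pd.DataFrame,
                           standardize: bool = True) -> RegressionResult:
    """OLS of tract ρ on annotation, SNP density, and their interaction.

    Annotation is treatment-coded. If SNP density is constant across tracts
    the density and interaction terms are dropped (flagged). Standardized
    coefficients (z-scored ρ and density) are reported alongside raw ones.
    """
    import statsmodels.formula.api as smf

    df = tracts.dropna(subset=["rho", "snp_density"]).copy()
    if df["annotation"].nunique() < 2:
        raise ValueError("need at least two annotation levels")
    collinear = np.isclose(df["snp_density"].var(ddof=0), 0.0)
    formula = ("rho ~ C(annotation)" if collinear
               else "rho ~ C(annotation) * snp_density")
    fit = smf.ols(formula, data=df).fit()
    std_params = None
    if standardize and not collinear:
        z = df.copy()
        for col in ("rho", "snp_density"):
            sd = z[col].std(ddof=0)
            z[col] = (z[col] - z[col].mean()) / (sd if sd > 0 else 1.0)
        std_params = smf.ols(formula, data=z).fit().params
    return RegressionResult(
        params=fit.params,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        dropped_interaction=collinear,
        standardized_params=std_params,
    )


# ---------------------------------------------------------------------------
# GC content


def gc_content_windows(sequence: str, window: int) -> pd.DataFrame:
    """GC fraction per non-overlapping window; N bases are excluded from
    the denominator (all-N windows get NaN)."""
    seq = np.frombuffer(sequence.upper().encode(), dtype="S1")
    L = seq.size
    n_win = int(np.ceil(L / window))
    rows = []
    for w in range(n_win):
        chunk = seq[w * window:min((w + 1) * window, L)]
        gc = np.sum((chunk == b"G") | (chunk == b"C"))
        at = np.sum((chunk == b"A") | (chunk == b"T"))
        denom = gc + at
        rows.append((w * window, min((w + 1) * window, L),
                     gc / denom if denom else np.nan))
    return pd.DataFrame(rows, columns=["start", "end", "gc"])


def gc_rho_correlation(sequence, landscape: RhoLandscape, window: int = 2000,
                       chromosome: str | None = None) -> tuple[float, float, pd.DataFrame]:
    """Spearman rank correlation of window GC content with window mean ρ.

    ``sequence`` is the genome string (or a FASTA path, read with Biopython).
    Returns (rho_spearman, p_value, per-window frame).
    """
    from .landscape import summarize_windows

    if not isinstance(sequence, str):
        sequence = str(sequence)
    if "\n" not in sequence and len(sequence) < 4096 and ("/" in sequence or sequence.endswith(".fa") or sequence.endswith(".fasta")):
        from Bio import SeqIO

        rec = next(SeqIO.parse(sequence, "fasta"))
        sequence = str(rec.seq)
    chrom = chromosome or landscape.chromosomes[0]
    gc = gc_content_windows(sequence, window)
    wins = summarize_windows(landscape, window)
    wins = wins[wins["chromosome"] == chrom].reset_index(drop=True)
    merged = gc.merge(wins[["start", "mean_rho"]], on="start", how="inner")
    merged = merged.dropna(subset=["gc", "mean_rho"])
    if len(merged) < 3:
        raise ValueError("need >=3 windows with both GC and rho")
    res = scipy.stats.spearmanr(merged["gc"], merged["mean_rho"])
    return float(res.statistic), float(res.pvalue), merged


def mann_whitney_rho(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U comparison of two sets of per-window ρ."""
    res = scipy.stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
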