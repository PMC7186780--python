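"""Hotspot detection from windowed ρ summaries, power evaluation against
planted truth maps, and annotation enrichment testing.

A hotspot is a run of adjacent windows whose mean ρ is at least ``fold``
times the bp-weighted mean of the surrounding windows (the flank, focal
window excluded), merged and retained if the run is at least ``min_len``
bp — the classic ≥2 kb, ≥5-fold-over-200-kb definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats


@dataclass
class HotspotRegion:
    chromosome: str
    start: int
    end: int
    mean_rho: float
    flank_rho: float
    fold: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _flank_means(means: np.ndarray, covered: np.ndarray, m: int) -> np.ndarray:
    """bp-weighted mean over the m windows on each side of every focal
    window (focal excluded, missing windows ignored, truncated at ends)."""
    w = np.where(np.isnan(means), 0.0, means * covered)
    c = np.where(np.isnan(means), 0.0, covered)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cc = np.concatenate([[0.0], np.cumsum(c)])
    n = len(means)
    i = np.arange(n)
    lo = np.maximum(i - m, 0)
    hi = np.minimum(i + m + 1, n)
    tot_w = cw[hi] - cw[lo] - w
    tot_c = cc[hi] - cc[lo] - c
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot_c > 0, tot_w / np.maximum(tot_c, 1e-300), np.nan)


def detect_hotspots(windows: pd.DataFrame, flank: int = 100_000, fold: float = 5.0,
                    min_len: int = 2000) -> list[HotspotRegion]:
    """Detect hotspot regions from a fixed-width window summary.

    Windows (as produced by :func:`rhoscape.summarize_windows`) are flagged
    when their mean ρ is ≥ ``fold`` × the bp-weighted mean ρ of windows
    within ``flank`` bp on each side (focal window excluded; flanks
    truncated at chromosome ends; windows with zero flank coverage or zero
    flank mean are skipped). Runs of adjacent flagged windows are merged
    and merged regions shorter than ``min_len`` dropped.
    """
    regions: list[HotspotRegion] = []
    for chrom, grp in windows.groupby("chromosome", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        widths = (grp["end"] - grp["start"]).to_numpy()
        if len(widths) > 1 and np.unique(widths[:-1]).size > 1:
            raise ValueError(f"{chrom}: windows of mixed widths")
        width = int(widths[0])
        m = max(1, flank // width)
        means = grp["mean_rho"].to_numpy(dtype=float)
        covered = grp["covered_bp"].to_numpy(dtype=float)
        fm = _flank_means(means, covered, m)
        with np.errstate(invalid="ignore"):
            flagged = (covered > 0) & ~np.isnan(means) & (fm > 0) & (means >= fold * fm)
        idx = np.flatnonzero(flagged)
        if idx.size == 0:
            continue
        # merge runs of consecutive window indices
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [idx.size - 1]])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for rs, re in zip(run_starts, run_ends):
            w0, w1 = idx[rs], idx[re]
            region_start, region_end = int(starts[w0]), int(ends[w1])
            if region_end - region_start < min_len:
                continue
            inside = slice(w0, w1 + 1)
            cov_in = covered[inside]
            mean_in = float(np.nansum(means[inside] * cov_in) / cov_in.sum())
            # flank of the merged region: windows within `flank` bp beyond
            # its edges
            lo = max(0, w0 - m)
            hi = min(len(means), w1 + 1 + m)
            out_idx = np.r_[lo:w0, w1 + 1:hi]
            cov_out = covered[out_idx]
            w_out = np.where(np.isnan(means[out_idx]), 0, means[out_idx] * cov_out)
            c_out = np.where(np.isnan(means[out_idx]), 0, cov_out)
            flank_mean = float(w_out.sum() / c_out.sum()) if c_out.sum() > 0 else np.nan
            regions.append(HotspotRegion(
                chromosome=chrom, start=region_start, end=region_end,
                mean_rho=mean_in, flank_rho=flank_mean,
                fold=mean_in / flank_mean if flank_mean and flank_mean > 0 else np.inf,
            ))
    return regions


def regions_to_bed(regions: list[HotspotRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t"
                     f"{r.mean_rho:.6g}\t{r.fold:.4g}\n")


def inter_hotspot_distances(regions: list[HotspotRegion]) -> np.ndarray:
    """Gaps (bp) between adjacent hotspot regions on each chromosome."""
    out = []
    by_chrom: dict[str, list[HotspotRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for rs in by_chrom.values():
        rs = sorted(rs, key=lambda r: r.start)
        out.extend(rs[i + 1].start - rs[i].end for i in range(len(rs) - 1))
    return np.array(out)


@dataclass
class PowerReport:
    """Detection power against a planted truth map."""

    power: float
    n_truth: int
    n_detected: int
    false_negatives: int
    by_fold: dict[float, float] = field(default_factory=dict)


def evaluate_power(truth, detected: list[HotspotRegion],
                   chromosome: str | None = None) -> PowerReport:
    """Fraction of truth hotspots overlapped (≥1 bp) by a detected region.

    ``truth`` is a TruthRecMap (or anything with ``.hotspots`` and
    ``.chromosome``); power is reported overall and stratified by fold.
    """
    chrom = chromosome or truth.chromosome
    regs = [(r.start, r.end) for r in detected if r.chromosome == chrom]
    hits_by_fold: dict[float, list[bool]] = {}
    n_hit = 0
    for s, e, f in truth.hotspots:
        hit = any(rs < e and re > s for rs, re in regs)
        n_hit += hit
        hits_by_fold.setdefault(float(f), []).append(hit)
    n = len(truth.hotspots)
    return PowerReport(
        power=n_hit / n if n else float("nan"),
        n_truth=n,
        n_detected=n_hit,
        false_negatives=n - n_hit,
        by_fold={f: float(np.mean(h)) for f, h in sorted(hits_by_fold.items())},
    )


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    table: np.ndarray
    infinite: bool = False


def enrichment_test(regions: list[HotspotRegion], annotation_mask: np.ndarray,
                    genome_length: int, chromosome: str | None = None,
                    unit: str = "bp", window: int = 2000) -> EnrichmentResult:
    """Fisher's exact test for hotspot × annotation association.

    With ``unit='bp'`` the 2×2 table counts base pairs cross-classified by
    hotspot membership and annotation membership. With ``unit='window'``
    the genome is cut into ``window``-bp windows, a window counting as
    hotspot if it overlaps any region and as annotated if at least half its
    bp are annotated. A zero off-diagonal cell yields an infinite odds
    ratio, flagged rather than capped.
    """
    annotation_mask = np.asarray(annotation_mask, dtype=bool)
    if annotation_mask.size != genome_length:
        raise ValueError("annotation_mask length must equal genome_length")
    hot = np.zeros(genome_length, dtype=bool)
    for r in regions:
        if chromosome is None or r.chromosome == chromosome:
            hot[max(0, r.start):min(genome_length, r.end)] = True
    if unit == "bp":
        a = int(np.sum(hot & annotation_mask))
        b = int(np.sum(hot & ~annotation_mask))
        c = int(np.sum(~hot & annotation_mask))
        d = genome_length - a - b - c
    elif unit == "window":
        n_win = int(np.ceil(genome_length / window))
        hw = np.zeros(n_win, dtype=bool)
        aw = np.zeros(n_win, dtype=bool)
        for w in range(n_win):
            seg = slice(w * window, min((w + 1) * window, genome_length))
            hw[w] = hot[seg].any()
            aw[w] = annotation_mask[seg].mean() >= 0.5
        a = int(np.sum(hw & aw)); b = int(np.sum(hw & ~aw))
        c = int(np.sum(~hw & aw)); d = int(np.sum(~hw & ~aw))
    else:
        raise ValueError("unit must be 'bp' or 'window'")
    table = np.array([[a, b], [c, d]])
    res = scipy.stats.fisher_exact(table, alternative="two-sided")
    infinite = (b == 0 or c == 0) and a > 0 and d > 0
    odds = np.inf if infinite else (a * d) / (b * c) if b * c > 0 else np.nan
    return EnrichmentResult(odds_ratio=float(odds), p_value=float(res.pvalue),
                            table=table, infinite=infinite)
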