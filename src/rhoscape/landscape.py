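"""Interval-based recombination landscapes (ρ/bp) and window summaries.

A landscape is an ordered set of non-overlapping intervals per chromosome,
each carrying a constant ρ per bp — the natural container for LD-based
estimates reported between adjacent SNPs. Interval files use the common
whitespace-delimited dialect ``left_snp right_snp mean [q0.025 q0.975]``
with 1-based half-open coordinates; internally everything is 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class LandscapeFormatError(ValueError):
    """Raised for malformed interval files (with the offending line number)."""


class RhoLandscape:
    """Per-chromosome sorted, non-overlapping (start, end, ρ/bp) intervals."""

    def __init__(self, intervals: dict[str, np.ndarray]):
        self._data: dict[str, np.ndarray] = {}
        for chrom, arr in intervals.items():
            arr = np.asarray(arr, dtype=float).reshape(-1, 3)
            order = np.argsort(arr[:, 0])
            arr = arr[order]
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError(f"{chrom}: empty or inverted interval")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError(f"{chrom}: overlapping intervals")
            if np.any(arr[:, 2] < 0):
                raise ValueError(f"{chrom}: negative rho")
            self._data[chrom] = arr

    @classmethod
    def from_intervals(cls, chromosome: str, intervals) -> "RhoLandscape":
        return cls({chromosome: np.asarray(intervals, dtype=float)})

    @property
    def chromosomes(self) -> list[str]:
        return list(self._data)

    def intervals(self, chromosome: str) -> np.ndarray:
        return self._data[chromosome]

    def span(self, chromosome: str) -> int:
        """Extent (max end coordinate) of the landscape on a chromosome."""
        return int(self._data[chromosome][-1, 1])

    def covered_bp(self, chromosome: str | None = None) -> float:
        chroms = [chromosome] if chromosome else self.chromosomes
        return float(sum((a[:, 1] - a[:, 0]).sum() for a in (self._data[c] for c in chroms)))

    def bp_weighted_mean(self, chromosome: str | None = None) -> float:
        """Mean ρ per bp weighted by interval length."""
        chroms = [chromosome] if chromosome else self.chromosomes
        num = den = 0.0
        for c in chroms:
            a = self._data[c]
            w = a[:, 1] - a[:, 0]
            num += float((a[:, 2] * w).sum())
            den += float(w.sum())
        return num / den

    def rho_at(self, chromosome: str, positions) -> np.ndarray:
        """ρ at 0-based positions; NaN outside covered intervals."""
        a = self._data[chromosome]
        pos = np.asarray(positions, dtype=float)
        idx = np.searchsorted(a[:, 0], pos, side="right") - 1
        idx = np.clip(idx, 0, len(a) - 1)
        inside = (pos >= a[idx, 0]) & (pos < a[idx, 1])
        out = np.where(inside, a[idx, 2], np.nan)
        return out

    def per_bp(self, chromosome: str) -> np.ndarray:
        """Dense per-bp ρ array over [0, span); NaN where uncovered."""
        return self.rho_at(chromosome, np.arange(self.span(chromosome)))

    def merged(self, other: "RhoLandscape") -> "RhoLandscape":
        data = {c: a.copy() for c, a in self._data.items()}
        for c, a in other._data.items():
            if c in data:
                raise ValueError(f"duplicate chromosome {c}")
            data[c] = a.copy()
        return RhoLandscape(data)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chromosomes:
            a = self._data[c]
            rows.append(pd.DataFrame({
                "chromosome": c,
                "start": a[:, 0].astype(int),
                "end": a[:, 1].astype(int),
                "rho": a[:, 2],
            }))
        return pd.concat(rows, ignore_index=True)


def read_rho_intervals(path, chromosome: str = "chr1") -> RhoLandscape:
    """Read a whitespace-delimited interval file into a landscape.

    Expected columns: ``left_snp right_snp mean [q0.025 q0.975]`` with
    1-based half-open [left_snp, right_snp) intervals. Header or version
    lines (any line whose first token is not a number) are skipped.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                left = float(tokens[0])
            except ValueError:
                continue  # header/version line
            if len(tokens) < 3:
                raise LandscapeFormatError(f"line {lineno}: expected >=3 columns")
            right, mean = float(tokens[1]), float(tokens[2])
            if right <= left:
                raise LandscapeFormatError(f"line {lineno}: right_snp <= left_snp")
            if mean < 0:
                raise LandscapeFormatError(f"line {lineno}: negative rho")
            if rows and left < rows[-1][1] + 1:
                raise LandscapeFormatError(
                    f"line {lineno}: interval overlaps or is out of order")
            rows.append((left - 1, right - 1, mean))
    if not rows:
        raise LandscapeFormatError("no interval rows found")
    return RhoLandscape.from_intervals(chromosome, rows)


def write_rho_intervals(landscape: RhoLandscape, path, chromosome: str | None = None) -> None:
    """Write one chromosome's intervals in the same dialect read back by
    :func:`read_rho_intervals` (quantile columns filled with the mean)."""
    chrom = chromosome or landscape.chromosomes[0]
    a = landscape.intervals(chrom)
    with open(path, "w") as fh:
        fh.write("left_snp right_snp mean p0.025 p0.975\n")
        for s, e, r in a:
            fh.write(f"{int(s) + 1} {int(e) + 1} {r:.10g} {r:.10g} {r:.10g}\n")


def summarize_windows(landscape: RhoLandscape, window: int = 2000) -> pd.DataFrame:
    """bp-weighted mean ρ in non-overlapping windows.

    Windows tile [0, span) per chromosome; the final partial window is kept
    with its true covered bp. Windows with zero coverage get NaN mean.
    """
    frames = []
    for chrom in landscape.chromosomes:
        a = landscape.intervals(chrom)
        span = landscape.span(chrom)
        n_win = int(np.ceil(span / window))
        wsum = np.zeros(n_win)
        wbp = np.zeros(n_win)
        for s, e, r in a:
            w0, w1 = int(s // window), int((e - 1) // window)
            for w in range(w0, w1 + 1):
                lo = max(s, w * window)
                hi = min(e, (w + 1) * window)
                wsum[w] += r * (hi - lo)
                wbp[w] += hi - lo
        with np.errstate(invalid="ignore"):
            mean = np.where(wbp > 0, wsum / np.maximum(wbp, 1e-300), np.nan)
        starts = np.arange(n_win) * window
        frames.append(pd.DataFrame({
            "chromosome": chrom,
            "start": starts,
            "end": np.minimum(starts + window, span),
            "mean_rho": mean,
            "covered_bp": wbp,
        }))
    return pd.concat(frames, ignore_index=True)


def windows_to_landscape(windows: pd.DataFrame) -> RhoLandscape:
    """Convert a window summary back into an interval landscape
    (covered windows only)."""
    data = {}
    for chrom, grp in windows.groupby("chromosome", sort=False):
        ok = grp["covered_bp"] > 0
        g = grp[ok]
        data[chrom] = np.column_stack([g["start"], g["end"], g["mean_rho"]])
    return RhoLandscape(data)


@dataclass
class ChromosomeStats:
    """Per-chromosome ρ summary and the ρ–length regression."""

    per_chromosome: pd.DataFrame  # chromosome, length, mean_rho
    genome_mean: float
    fold_range: float
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    p_value: float | None = None
    regression_defined: bool = False


def chromosome_stats(landscape: RhoLandscape) -> ChromosomeStats:
    """bp-weighted mean ρ per chromosome, genome mean, fold range, and an
    OLS regression of chromosome mean ρ on chromosome length.

    The regression needs ≥3 chromosomes for a p-value; otherwise it is
    flagged undefined.
    """
    import scipy.stats

    rows = []
    for chrom in landscape.chromosomes:
        rows.append({
            "chromosome": chrom,
            "length": landscape.span(chrom),
            "mean_rho": landscape.bp_weighted_mean(chrom),
        })
    df = pd.DataFrame(rows)
    means = df["mean_rho"].to_numpy()
    stats = ChromosomeStats(
        per_chromosome=df,
        genome_mean=landscape.bp_weighted_mean(),
        fold_range=float(means.max() / means.min()) if means.min() > 0 else float("inf"),
    )
    if len(df) >= 3:
        res = scipy.stats.linregress(df["length"], df["mean_rho"])
        stats.slope = float(res.slope)
        stats.intercept = float(res.intercept)
        stats.r_squared = float(res.rvalue ** 2)
        stats.p_value = float(res.pvalue)
        stats.regression_defined = True
    return stats
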