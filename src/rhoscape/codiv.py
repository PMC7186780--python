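"""Crossover densities (cM/Mb) binned by ρ or by nucleotide diversity.

Crossovers observed in tetrad offspring are converted to a physical
recombination rate per bin: cM/Mb = (CO count / n individuals × 100) /
(bin bp / 10⁶). Binning by LD-based ρ checks that the population landscape
reflects real crossover placement; binning by silent-site θπ probes
selection at linked sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .haplotypes import HaplotypeBlock
from .landscape import RhoLandscape


@dataclass
class CrossoverTable:
    """Crossover intervals (chromosome, start, end, offspring_id)."""

    df: pd.DataFrame
    n_individuals: int

    def __post_init__(self):
        required = {"chromosome", "start", "end", "offspring_id"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"crossover table needs columns {sorted(required)}")
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise ValueError("crossover intervals need start < end")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")

    def __len__(self) -> int:
        return len(self.df)

    def midpoints(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, n_individuals: int) -> "CrossoverTable":
        return cls(pd.read_csv(path, sep="\t"), n_individuals)


def _cm_per_mb(co_count: np.ndarray, bp: np.ndarray, n_individuals: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = (co_count / n_individuals * 100.0) / (bp / 1e6)
    return np.where(bp > 0, rate, np.nan)


def rho_binned_co_rate(landscape: RhoLandscape, crossovers: CrossoverTable,
                       n_bins: int = 50, rho_range: tuple[float, float] = (0.0, 0.06),
                       ) -> pd.DataFrame:
    """Crossover rate (cM/Mb) within equal-width ρ bins.

    Every covered bp is assigned to a bin by its interval's ρ; each CO is
    assigned by the ρ at its interval midpoint. Bins are half-open
    [lo, hi); values at or above the top go to an overflow row, reported
    but flagged. Zero-bp bins get NaN rates. CO midpoints falling outside
    landscape coverage are counted as unassigned (``bin = -1``).
    """
    lo, hi = rho_range
    edges = np.linspace(lo, hi, n_bins + 1)

    def bin_of(vals):
        v = np.asarray(vals, dtype=float)
        b = np.searchsorted(edges, v, side="right") - 1
        b = np.where(v >= hi, n_bins, b)          # overflow bin
        b = np.where(np.isnan(v) | (v < lo), -1, b)
        return b.astype(int)

    bp = np.zeros(n_bins + 1)
    for chrom in landscape.chromosomes:
        a = landscape.intervals(chrom)
        b = bin_of(a[:, 2])
        ok = b >= 0
        np.add.at(bp, b[ok], (a[ok, 1] - a[ok, 0]))

    counts = np.zeros(n_bins + 1)
    unassigned = 0
    for chrom, grp in crossovers.df.groupby("chromosome", sort=False):
        mids = ((grp["start"] + grp["end"]) // 2).to_numpy()
        if chrom in landscape.chromosomes:
            rho = landscape.rho_at(chrom, mids)
        else:
            rho = np.full(len(mids), np.nan)
        b = bin_of(rho)
        unassigned += int((b < 0).sum())
        ok = b >= 0
        np.add.at(counts, b[ok], 1)

    df = pd.DataFrame({
        "bin_lo": np.append(edges[:-1], hi),
        "bin_hi": np.append(edges[1:], np.inf),
        "bin_mid": np.append((edges[:-1] + edges[1:]) / 2, np.nan),
        "bp": bp,
        "co_count": counts.astype(int),
        "cm_per_mb": _cm_per_mb(counts, bp, crossovers.n_individuals),
        "overflow": [False] * n_bins + [True],
    })
    df.attrs["unassigned_cos"] = unassigned
    return df


def theta_pi_windows(block: HaplotypeBlock, silent_mask: np.ndarray,
                     window: int = 10_000, min_silent: int = 500) -> pd.DataFrame:
    """Silent-site θπ in non-overlapping windows.

    θπ per window = Σ over silent SNPs of c(k−c)/C(k,2), divided by the
    number of silent sites in the window; windows with fewer than
    ``min_silent`` silent sites are dropped.
    """
    silent_mask = np.asarray(silent_mask, dtype=bool)
    L = block.sequence_length
    if silent_mask.size != L:
        raise ValueError("silent_mask length must equal block.sequence_length")
    c, k = block.derived_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(k >= 2, c * (k - c) / np.maximum(k * (k - 1) / 2.0, 1e-300), 0.0)
    snp_silent = silent_mask[block.positions]
    n_win = int(np.ceil(L / window))
    silent_counts = np.array([
        silent_mask[w * window:min((w + 1) * window, L)].sum() for w in range(n_win)
    ])
    pi_sums = np.zeros(n_win)
    widx = (block.positions // window).astype(int)
    np.add.at(pi_sums, widx[snp_silent], per_site[snp_silent])
    starts = np.arange(n_win) * window
    df = pd.DataFrame({
        "chromosome": block.chromosome,
        "start": starts,
        "end": np.minimum(starts + window, L),
        "silent_sites": silent_counts,
        "theta_pi": np.where(silent_counts > 0,
                             pi_sums / np.maximum(silent_counts, 1), np.nan),
    })
    return df[df["silent_sites"] >= min_silent].reset_index(drop=True)


@dataclass
class BinnedRateRegression:
    """OLS of per-bin cM/Mb on the bin midpoint."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_bins: int


def diversity_binned_co_rate(div_windows: pd.DataFrame, crossovers: CrossoverTable,
                             n_bins: int = 50, pi_range: tuple[float, float] = (0.0, 0.1),
                             min_bin_bp: float = 200_000,
                             ) -> tuple[pd.DataFrame, BinnedRateRegression | None]:
    """Crossover rate per θπ bin, plus a linear fit of rate on diversity.

    Windows contribute their genomic bp to the bin of their θπ; each CO is
    assigned by the mean θπ of retained windows overlapping its interval
    (COs overlapping no retained window are unassigned). Bins aggregating
    less than ``min_bin_bp`` are discarded before the regression; the
    overflow bin is reported but excluded.
    """
    lo, hi = pi_range
    edges = np.linspace(lo, hi, n_bins + 1)

    def bin_of(v):
        v = np.asarray(v, dtype=float)
        b = np.searchsorted(edges, v, side="right") - 1
        b = np.where(v >= hi, n_bins, b)
        return np.where(np.isnan(v) | (v < lo), -1, b).astype(int)

    bp = np.zeros(n_bins + 1)
    wb = bin_of(div_windows["theta_pi"])
    ok = wb >= 0
    np.add.at(bp, wb[ok], (div_windows["end"] - div_windows["start"]).to_numpy()[ok])

    counts = np.zeros(n_bins + 1)
    unassigned = 0
    for chrom, grp in crossovers.df.groupby("chromosome", sort=False):
        wins = div_windows[div_windows["chromosome"] == chrom]
        ws, we = wins["start"].to_numpy(), wins["end"].to_numpy()
        pis = wins["theta_pi"].to_numpy()
        for co in grp.itertuples():
            overlap = (ws < co.end) & (we > co.start)
            if not overlap.any():
                unassigned += 1
                continue
            b = bin_of([pis[overlap].mean()])[0]
            if b < 0:
                unassigned += 1
            else:
                counts[b] += 1

    rate = _cm_per_mb(counts, bp, crossovers.n_individuals)
    df = pd.DataFrame({
        "bin_lo": np.append(edges[:-1], hi),
        "bin_hi": np.append(edges[1:], np.inf),
        "bin_mid": np.append((edges[:-1] + edges[1:]) / 2, np.nan),
        "bp": bp,
        "co_count": counts.astype(int),
        "cm_per_mb": rate,
        "overflow": [False] * n_bins + [True],
        "retained": np.append(bp[:-1] >= min_bin_bp, False),
    })
    df.attrs["unassigned_cos"] = unassigned

    fit = None
    sel = df["retained"] & ~df["cm_per_mb"].isna()
    if sel.sum() >= 3:
        res = scipy.stats.linregress(df.loc[sel, "bin_mid"], df.loc[sel, "cm_per_mb"])
        fit = BinnedRateRegression(
            slope=float(res.slope), intercept=float(res.intercept),
            r_squared=float(res.rvalue ** 2), p_value=float(res.pvalue),
            n_bins=int(sel.sum()),
        )
    return df, fit
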