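"""Pairwise linkage disequilibrium, the Hill–Weir decay expectation, and
LD-based estimation of the population recombination rate ρ = 2Nₑr.

The decay model is the classical sampling expectation for r² between two
biallelic loci separated by scaled distance Γ = ρ·d in a sample of n
haplotypes:

    E(r²) = (10+Γ)/(22+13Γ+Γ²) · [1 + (3+Γ)(12+12Γ+Γ²) / (n(22+13Γ+Γ²))]

which tends to 10/22 as Γ→0 (plus the 1/n sampling term) and to 1/n as
Γ→∞. Fitting this curve to observed (distance, r²) pairs by nonlinear
least squares yields ρ̂ per bp; applying the fit window-by-window gives a
coarse recombination landscape directly from haplotype data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .haplotypes import HaplotypeBlock
from .landscape import RhoLandscape


def expected_r2(gamma, n: int):
    """Hill–Weir expectation of r² at scaled distance Γ for n sampled
    haplotypes. Vectorized over ``gamma``."""
    g = np.asarray(gamma, dtype=float)
    q = 22.0 + 13.0 * g + g * g
    adj = 1.0 + (3.0 + g) * (12.0 + 12.0 * g + g * g) / (n * q)
    out = (10.0 + g) / q * adj
    return out if out.ndim else float(out)


def pair_stats(genotypes: np.ndarray, idx1: np.ndarray, idx2: np.ndarray,
               chunk: int = 200_000) -> tuple[np.ndarray, np.ndarray]:
    """(r², four-gamete indicator) for site-index pairs of a haploid matrix.

    Missing calls (−1) are dropped pairwise; pairs monomorphic among
    complete observations get NaN in both outputs.
    r² = D²/(p(1−p)q(1−q)), D = p₁₁ − pq. The four-gamete indicator is 1
    when all four haplotypes (00, 01, 10, 11) are observed — evidence of at
    least one historical crossover between the sites.
    """
    m = len(idx1)
    r2_out = np.full(m, np.nan)
    fgv_out = np.full(m, np.nan)
    G = genotypes
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        X = G[:, idx1[lo:hi]]
        Y = G[:, idx2[lo:hi]]
        valid = (X >= 0) & (Y >= 0)
        k = valid.sum(axis=0).astype(float)
        Xv = np.where(valid, X, 0).astype(float)
        Yv = np.where(valid, Y, 0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            sx = Xv.sum(axis=0)
            sy = Yv.sum(axis=0)
            s11 = (Xv * Yv).sum(axis=0)
            p = sx / k
            q = sy / k
            p11 = s11 / k
            D = p11 - p * q
            denom = p * (1 - p) * q * (1 - q)
            ok = (denom > 0) & (k >= 2)
            r2 = np.where(ok, D * D / np.where(denom > 0, denom, 1.0), np.nan)
        # haplotype counts: n11=s11, n10=sx-s11, n01=sy-s11, n00=k-sx-sy+s11
        four = (s11 > 0) & (sx - s11 > 0) & (sy - s11 > 0) & (k - sx - sy + s11 > 0)
        r2_out[lo:hi] = r2
        fgv_out[lo:hi] = np.where(ok, four.astype(float), np.nan)
    return r2_out, fgv_out


def r2_for_pairs(genotypes: np.ndarray, idx1: np.ndarray, idx2: np.ndarray,
                 chunk: int = 200_000) -> np.ndarray:
    """r² for explicit site-index pairs (see :func:`pair_stats`)."""
    return pair_stats(genotypes, idx1, idx2, chunk=chunk)[0]


def pairwise_r2(block: HaplotypeBlock, max_dist: int = 100_000,
                max_pairs: int | None = None, seed: int = 0) -> pd.DataFrame:
    """r² for all SNP pairs within ``max_dist`` bp.

    Returns a frame with columns pos1, pos2, d, r2 (pairs where either site
    is monomorphic among complete observations are dropped). ``max_pairs``
    optionally subsamples pairs reproducibly before computing r².
    """
    pos = block.positions
    S = pos.size
    hi = np.searchsorted(pos, pos + max_dist, side="right")
    counts = np.maximum(hi - np.arange(1, S + 1), 0)
    total = int(counts.sum())
    if max_pairs is not None and total > max_pairs:
        # draw flat pair ranks without materializing every pair (the full
        # enumeration can run to 10^8+ pairs at chromosome scale)
        rng = np.random.default_rng(seed)
        flat = np.unique(rng.integers(0, total, size=max_pairs))
        offsets = np.concatenate([[0], np.cumsum(counts)])
        idx1 = np.searchsorted(offsets, flat, side="right") - 1
        idx2 = (flat - offsets[idx1]) + idx1 + 1
    else:
        idx1 = np.repeat(np.arange(S), counts)
        idx2 = (np.concatenate([np.arange(i + 1, h) for i, h in enumerate(hi)])
                if S else np.array([], int))
    r2 = r2_for_pairs(block.genotypes, idx1, idx2)
    ok = ~np.isnan(r2)
    return pd.DataFrame({
        "pos1": pos[idx1[ok]],
        "pos2": pos[idx2[ok]],
        "d": pos[idx2[ok]] - pos[idx1[ok]],
        "r2": r2[ok],
    })


@dataclass
class LDDecayModel:
    """Fitted single-parameter LD decay curve."""

    rho_hat: float
    n: int
    residual_ss: float
    converged: bool
    n_pairs: int
    flags: list[str] = field(default_factory=list)

    def curve(self, d):
        return expected_r2(self.rho_hat * np.asarray(d, dtype=float), self.n)


def bin_pairs(d: np.ndarray, r2: np.ndarray, bin_width: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean r² in distance bins; returns (bin-centre distances, means)."""
    b = (np.asarray(d) // bin_width).astype(int)
    uniq = np.unique(b)
    means = np.array([r2[b == u].mean() for u in uniq])
    centres = (uniq + 0.5) * bin_width
    return centres, means


def fit_ld_decay(d, r2, n: int, rho_init: float = 1e-3,
                 rho_bounds: tuple[float, float] = (0.0, 10.0),
                 bin_width: int | None = None) -> LDDecayModel:
    """Least-squares fit of the decay expectation to observed (d, r²) pairs.

    A single parameter ρ ≥ 0 is estimated with bounded least squares
    (initial value ``rho_init``). With ``bin_width`` the fit uses
    distance-binned mean r² instead of raw pairs. Degenerate inputs (a
    single distance, or zero variance in r²) are flagged and the fit marked
    unconverged.
    """
    d = np.asarray(d, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    ok = ~(np.isnan(d) | np.isnan(r2))
    d, r2 = d[ok], r2[ok]
    flags = []
    if d.size < 2:
        raise ValueError("need >=2 pairs to fit LD decay")
    if bin_width:
        d, r2 = bin_pairs(d, r2, bin_width)
    if np.unique(d).size < 2:
        flags.append("single_distance")
    if np.ptp(r2) == 0:
        flags.append("constant_r2")

    def resid(theta):
        return expected_r2(theta[0] * d, n) - r2

    res = least_squares(resid, x0=[rho_init], bounds=([rho_bounds[0]], [rho_bounds[1]]))
    converged = bool(res.success) and not flags
    return LDDecayModel(
        rho_hat=float(res.x[0]),
        n=n,
        residual_ss=float(2.0 * res.cost),
        converged=converged,
        n_pairs=int(d.size),
        flags=flags,
    )


@dataclass
class DecayStats:
    """Distances summarizing a fitted decay curve."""

    start_r2: float
    half_decay_bp: int | None
    baseline_bp: int | None
    baseline_r2: float | None
    flags: list[str] = field(default_factory=list)


def _curve_slope(model: LDDecayModel, d: np.ndarray) -> np.ndarray:
    """Central-difference d E(r²)/dd at integer distances (per bp)."""
    d = np.asarray(d, dtype=float)
    return (model.curve(d + 1.0) - model.curve(d - 1.0)) / 2.0


def decay_statistics(model: LDDecayModel, scan_limit: int = 2_000_000,
                     slope_tol: float = 0.5e-5) -> DecayStats:
    """Half-decay distance and baseline of a fitted decay curve.

    The starting value is the curve at d = 1 bp. The half-decay distance is
    the smallest integer d with E(r²) ≤ start/2 (bisection; the curve is
    monotone decreasing in Γ). The baseline distance is the smallest d at
    which the magnitude of the local slope drops below ``slope_tol`` per bp
    — i.e. rounds to zero at five decimal digits — and baseline_r2 is the
    curve value there. A flat curve (ρ̂ = 0, or no decay within
    ``scan_limit``) leaves the distances undefined.
    """
    start = float(model.curve(1))
    stats = DecayStats(start_r2=start, half_decay_bp=None, baseline_bp=None,
                       baseline_r2=None)
    if model.rho_hat <= 0:
        stats.flags.append("flat_curve")
        return stats

    def bisect_first(pred) -> int | None:
        # smallest integer d in [1, scan_limit] with pred(d) True,
        # assuming pred is monotone (False ... True)
        if not pred(scan_limit):
            return None
        lo, hi = 1, scan_limit
        if pred(lo):
            return lo
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if pred(mid):
                hi = mid
            else:
                lo = mid
        return hi

    half = bisect_first(lambda d: model.curve(d) <= start / 2.0)
    if half is None:
        stats.flags.append("half_decay_beyond_scan_limit")
    stats.half_decay_bp = half

    base = bisect_first(lambda d: abs(_curve_slope(model, np.array([d]))[0]) < slope_tol)
    if base is None:
        stats.flags.append("baseline_beyond_scan_limit")
    else:
        stats.baseline_r2 = float(model.curve(base))
    stats.baseline_bp = base
    return stats


def _pava_decreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators fit, non-increasing."""
    vals: list[float] = []
    wts: list[float] = []
    cnts: list[int] = []
    for yi, wi in zip(y, w):
        vals.append(float(yi)); wts.append(float(wi)); cnts.append(1)
        while len(vals) > 1 and vals[-2] < vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wts[-2] += wts[-1]; cnts[-2] += cnts[-1]; vals[-2] = v
            vals.pop(); wts.pop(); cnts.pop()
    out = []
    for v, c in zip(vals, cnts):
        out.extend([v] * c)
    return np.array(out)


@dataclass
class R2Calibration:
    """Simulation-calibrated moments of r² as a function of (distance, ρ).

    The closed-form decay expectation holds for unconditioned pairs; under a
    minor-allele-frequency filter and finite θ the true conditional mean
    E(r² | d, ρ) deviates from it in a compressive way (inflated at low ρ,
    attenuated at high ρ). This table is built once per study condition
    (n haplotypes, θ, MAF filter) by simulating uniform-ρ coalescent samples
    over a ladder of ρ values and recording the mean and variance of r² in
    log-spaced distance bins; estimation then inverts the empirical mapping
    instead of the formula. ``mean[i, j]``/``var[i, j]`` index distance bin
    i and a fine log-spaced ρ grid j.
    """

    log_d_edges: np.ndarray
    log_rho_grid: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    n_samples: int
    theta: float
    maf_min: float | None
    #: mean four-gamete-violation rate per (distance bin, rho); the FGV
    #: indicator keeps discriminating rates where r² has saturated at its
    #: sampling floor
    fgv_mean: np.ndarray | None = None

    def d_bin(self, d) -> np.ndarray:
        ld = np.log10(np.maximum(np.asarray(d, dtype=float), 1.0))
        b = np.searchsorted(self.log_d_edges, ld, side="right") - 1
        return np.clip(b, 0, len(self.log_d_edges) - 2)

    def _rho_index(self, rho):
        lr = np.log10(np.clip(np.asarray(rho, dtype=float), 1e-8, None))
        g = self.log_rho_grid
        x = np.clip((lr - g[0]) / (g[1] - g[0]), 0, len(g) - 1 - 1e-9)
        j = x.astype(int)
        return j, x - j

    def predict(self, d_bin: np.ndarray, rho) -> np.ndarray:
        """Mean r² for pairs in the given distance bins at local rate rho."""
        j, f = self._rho_index(rho)
        return self.mean[d_bin, j] * (1 - f) + self.mean[d_bin, j + 1] * f

    def weights(self, d_bin: np.ndarray, rho) -> np.ndarray:
        """Inverse-variance weights for least squares."""
        j, f = self._rho_index(rho)
        v = self.var[d_bin, j] * (1 - f) + self.var[d_bin, j + 1] * f
        return 1.0 / np.maximum(v, 1e-4)

    def predict_fgv(self, d_bin: np.ndarray, rho) -> np.ndarray:
        """Mean four-gamete-violation rate at the given (distance, rho)."""
        j, f = self._rho_index(rho)
        return self.fgv_mean[d_bin, j] * (1 - f) + self.fgv_mean[d_bin, j + 1] * f


def calibrate_r2(n_samples: int = 19, theta: float = 0.03,
                 maf_min: float | None = 0.1,
                 rho_ladder=(0.0002, 0.0005, 0.001, 0.002, 0.005, 0.01,
                             0.02, 0.05, 0.1, 0.2),
                 reps: int = 3, seq_length: int = 250_000,
                 max_dist: int = 10_000, n_d_bins: int = 14,
                 pairs_per_sim: int = 80_000, seed: int = 2_020) -> R2Calibration:
    """Build an :class:`R2Calibration` table under given study conditions.

    Simulates ``reps`` uniform-map coalescent samples at every ladder ρ,
    applies the same MAF filter the estimator will see, computes pairwise r²
    out to ``max_dist``, and tabulates mean and variance per (distance bin,
    ρ). Columns are made monotone non-increasing in ρ (pool-adjacent-
    violators) and resampled onto a fine log-ρ grid for fast lookup.
    """
    from .simulate import SimConfig, simulate_haplotypes

    rng = np.random.default_rng(seed)
    log_d_edges = np.linspace(0.0, np.log10(max_dist), n_d_bins + 1)
    ladder = np.asarray(rho_ladder, dtype=float)
    raw_mean = np.full((n_d_bins, len(ladder)), np.nan)
    raw_var = np.full((n_d_bins, len(ladder)), np.nan)
    raw_fgv = np.full((n_d_bins, len(ladder)), np.nan)
    for jr, rho in enumerate(ladder):
        ds, r2s, fgvs = [], [], []
        # coalescent cost grows superlinearly with rho x length; shorter
        # sequences at high rho sample the same (d, rho) cells for a tiny
        # fraction of the time
        L = int(min(seq_length, max(50_000, 10_000 / rho)))
        for _ in range(reps):
            cfg = SimConfig(n_samples=n_samples, seq_length=L,
                            theta=theta, background_rho=float(rho),
                            hotspot_spec=(), seed=int(rng.integers(2**31)))
            blk = simulate_haplotypes(cfg)
            if maf_min is not None:
                blk = blk.filter_maf(maf_min)
            pos = blk.positions
            S = pos.size
            hi = np.searchsorted(pos, pos + max_dist, side="right")
            counts = np.maximum(hi - np.arange(1, S + 1), 0)
            idx1 = np.repeat(np.arange(S), counts)
            idx2 = (np.concatenate([np.arange(i + 1, h) for i, h in enumerate(hi)])
                    if S else np.array([], int))
            if len(idx1) > pairs_per_sim:
                take = rng.choice(len(idx1), size=pairs_per_sim, replace=False)
                idx1, idx2 = idx1[take], idx2[take]
            r2, fgv = pair_stats(blk.genotypes, idx1, idx2)
            ok = ~np.isnan(r2)
            ds.append((pos[idx2[ok]] - pos[idx1[ok]]).astype(float))
            r2s.append(r2[ok])
            fgvs.append(fgv[ok])
        d = np.concatenate(ds); r2 = np.concatenate(r2s); fgv = np.concatenate(fgvs)
        b = np.clip(np.searchsorted(log_d_edges, np.log10(np.maximum(d, 1.0)),
                                    side="right") - 1, 0, n_d_bins - 1)
        for i in range(n_d_bins):
            sel = b == i
            if sel.sum() >= 50:
                raw_mean[i, jr] = r2[sel].mean()
                raw_var[i, jr] = r2[sel].var()
                raw_fgv[i, jr] = fgv[sel].mean()
    # fill sparse cells from neighbouring distance bins, then enforce
    # monotonicity along rho (r² decreasing, FGV increasing)
    for arr in (raw_mean, raw_var, raw_fgv):
        for jr in range(len(ladder)):
            col = arr[:, jr]
            if np.isnan(col).all():
                raise RuntimeError("calibration produced an empty rho column")
            idx = np.flatnonzero(~np.isnan(col))
            arr[:, jr] = np.interp(np.arange(n_d_bins), idx, col[idx])
    for i in range(n_d_bins):
        raw_mean[i] = _pava_decreasing(raw_mean[i], np.ones(len(ladder)))
        raw_fgv[i] = -_pava_decreasing(-raw_fgv[i], np.ones(len(ladder)))
    # resample onto a fine log-rho grid
    log_lad = np.log10(ladder)
    log_rho_grid = np.linspace(log_lad[0], log_lad[-1], 160)
    mean = np.empty((n_d_bins, len(log_rho_grid)))
    var = np.empty_like(mean)
    fgv_mean = np.empty_like(mean)
    for i in range(n_d_bins):
        mean[i] = np.interp(log_rho_grid, log_lad, raw_mean[i])
        var[i] = np.interp(log_rho_grid, log_lad, raw_var[i])
        fgv_mean[i] = np.interp(log_rho_grid, log_lad, raw_fgv[i])
    return R2Calibration(log_d_edges=log_d_edges, log_rho_grid=log_rho_grid,
                         mean=mean, var=var, n_samples=n_samples, theta=theta,
                         maf_min=maf_min, fgv_mean=fgv_mean)


def _fit_rho_1d(fun, lo: float = 1e-6, hi: float = 1.0, n_grid: int = 25) -> float:
    """Minimize a 1-D objective over ρ on a log grid, then refine locally.

    The calibrated SSE surface is flat outside the calibration range, which
    defeats plain bounded Brent search; a coarse log-spaced scan brackets
    the global minimum first.
    """
    from scipy.optimize import minimize_scalar

    grid = np.geomspace(lo, hi, n_grid)
    vals = np.array([fun(x) for x in grid])
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_grid - 1)]
    if a == b:
        return float(grid[k])
    res = minimize_scalar(fun, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-7})
    return float(res.x) if res.fun <= vals[k] else float(grid[k])


def calibrate_window_bias(calibration: R2Calibration, background_rho: float = 0.001,
                          reps: int = 3, seq_length: int = 250_000,
                          hotspot_spec=None, seed: int = 4_040,
                          **window_kwargs) -> float:
    """Additive skew offset δ for the windowed estimator.

    Per-window ρ̂ is right-skewed: its median tracks the truth but its mean
    sits above it, which inflates any flank average computed from the
    estimated landscape. This runs the windowed estimator on simulations at
    the study conditions and solves (by bisection) for the offset δ such
    that, over windows whose true rate is the background, mean(max(ρ̂ − δ,
    0)) equals the true background rate. Subtracting δ from every window
    makes background flank means unbiased while barely touching
    hotspot-scale values.

    ``hotspot_spec`` should describe the deployment landscape (default: the
    study's eight-hotspot map scaled to ``seq_length``): hotspot shoulders
    leak a little estimated rate into nearby background windows, so an
    offset calibrated on purely uniform maps under-corrects. Pass the same
    window parameters that will be used on the real data.
    """
    from .simulate import DEFAULT_HOTSPOT_SPEC, SimConfig, build_truth_map, simulate_haplotypes

    if hotspot_spec is None:
        # same planted-hotspot density as the 1-Mb study map
        k = max(1, round(len(DEFAULT_HOTSPOT_SPEC) * seq_length / 1_000_000))
        hotspot_spec = DEFAULT_HOTSPOT_SPEC[:k]
    rng = np.random.default_rng(seed)
    window = window_kwargs.get("window", 2000)
    ests = []
    for _ in range(reps):
        cfg = SimConfig(n_samples=calibration.n_samples, seq_length=seq_length,
                        theta=calibration.theta, background_rho=background_rho,
                        hotspot_spec=tuple(hotspot_spec),
                        seed=int(rng.integers(2**31)))
        truth = build_truth_map(cfg)
        blk = simulate_haplotypes(cfg, truth)
        if calibration.maf_min is not None:
            blk = blk.filter_maf(calibration.maf_min)
        lands = windowed_rho(blk, calibration=calibration,
                             seed=int(rng.integers(2**31)), **window_kwargs)
        arr = lands.intervals(cfg.chromosome)
        # keep windows that lie entirely in background sequence
        is_bg = np.ones(len(arr), dtype=bool)
        for s, e, _ in truth.hotspots:
            is_bg &= (arr[:, 1] <= s) | (arr[:, 0] >= e)
        ests.append(arr[is_bg, 2])
    v = np.concatenate(ests)
    if v.mean() <= background_rho:
        return 0.0
    lo, hi = 0.0, float(v.mean())
    for _ in range(60):
        mid = (lo + hi) / 2
        if np.maximum(v - mid, 0.0).mean() > background_rho:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def apply_window_bias(landscape: RhoLandscape, delta: float) -> RhoLandscape:
    """Subtract a calibrated skew offset from every window (floored at 0)."""
    data = {}
    for chrom in landscape.chromosomes:
        a = landscape.intervals(chrom).copy()
        a[:, 2] = np.maximum(a[:, 2] - delta, 0.0)
        data[chrom] = a
    return RhoLandscape(data)


def _collect_window_pairs(block: HaplotypeBlock, window: int, max_dist: int,
                          short_dist: int, max_short: int, max_long: int,
                          rng: np.random.Generator):
    """Stratified per-window pair sample: left member assigns the window;
    short pairs (within ``short_dist``) and longer spans are capped
    separately so local decay signal is not swamped by the more numerous
    long pairs."""
    pos = block.positions
    L = block.sequence_length
    n_win = int(np.ceil(L / window))
    hi_all = np.searchsorted(pos, pos + max_dist, side="right")
    I1, I2 = [], []
    for w in range(n_win):
        a = np.searchsorted(pos, w * window, side="left")
        b = np.searchsorted(pos, min((w + 1) * window, L), side="left")
        p1, p2 = [], []
        for i in range(a, b):
            h = hi_all[i]
            if h > i + 1:
                p1.append(np.full(h - i - 1, i))
                p2.append(np.arange(i + 1, h))
        if not p1:
            continue
        i1 = np.concatenate(p1); i2 = np.concatenate(p2)
        d = pos[i2] - pos[i1]
        for sel, cap in ((d <= short_dist, max_short), (d > short_dist, max_long)):
            ii1, ii2 = i1[sel], i2[sel]
            if len(ii1) > cap:
                take = rng.choice(len(ii1), size=cap, replace=False)
                ii1, ii2 = ii1[take], ii2[take]
            if len(ii1):
                I1.append(ii1); I2.append(ii2)
    if not I1:
        raise ValueError("no SNP pairs within max_dist")
    return np.concatenate(I1), np.concatenate(I2), n_win


def windowed_rho(block: HaplotypeBlock, window: int = 2000, n: int | None = None,
                 calibration: R2Calibration | None = None,
                 max_dist: int = 10_000, short_dist: int = 2000,
                 max_short: int = 3000, max_long: int = 2000,
                 min_pairs: int = 30, n_passes: int = 2,
                 rho_max: float = 1.0, seed: int = 0) -> RhoLandscape:
    """Windowed ρ estimation from local LD decay.

    Each non-overlapping window receives a ρ̂ per bp estimated from SNP
    pairs, giving a coarse recombination landscape directly from haplotype
    data. Two modes:

    * **moment fit** (``calibration=None``): pairs whose left member lies in
      the window are fitted against the closed-form decay expectation with
      :func:`fit_ld_decay`. Simple and dependency-free, but biased
      compressively under MAF filtering and blind to ρ variation across a
      pair's span.
    * **calibrated deconvolution** (with an :class:`R2Calibration`): a
      pair's scaled length Γ is modelled as Σ_w ρ_w × overlap(pair, w), so
      spans crossing window boundaries inform every window they touch;
      window rates are estimated jointly by inverse-variance-weighted
      least squares against the calibrated E(r² | d, ρ) surface, solved by
      coordinate descent (``n_passes`` sweeps).

    Windows with fewer than ``min_pairs`` usable pairs, or whose fit runs
    into ``rho_max`` (LD already at its sampling floor, rate unidentifiable),
    are left missing. Returns an interval landscape over estimated windows.
    """
    if n is None:
        n = block.n_samples
    pos = block.positions
    L = block.sequence_length
    rng = np.random.default_rng(seed)
    idx1, idx2, n_win = _collect_window_pairs(
        block, window, max_dist, short_dist, max_short, max_long, rng)
    r2, fgv = pair_stats(block.genotypes, idx1, idx2)
    ok = ~np.isnan(r2)
    idx1, idx2, r2, fgv = idx1[ok], idx2[ok], r2[ok], fgv[ok]
    pa = pos[idx1].astype(float)
    pb = pos[idx2].astype(float)
    w0 = (pa // window).astype(int)

    if calibration is None:
        intervals = []
        for w in range(n_win):
            sel = w0 == w
            if sel.sum() < min_pairs:
                continue
            model = fit_ld_decay(pb[sel] - pa[sel], r2[sel], n,
                                 rho_bounds=(0.0, rho_max))
            if model.rho_hat >= 0.9 * rho_max:
                continue
            intervals.append((w * window, min((w + 1) * window, L), model.rho_hat))
        if not intervals:
            raise ValueError("no window had enough informative pairs")
        return RhoLandscape.from_intervals(block.chromosome, intervals)

    cal = calibration
    dbin = cal.d_bin(pb - pa)
    d_span = pb - pa
    # per-pair overlap with each window its span touches
    kmax = int(max_dist // window) + 2
    ov = np.zeros((len(pa), kmax), dtype=np.float32)
    widx = np.zeros((len(pa), kmax), dtype=np.int32)
    for k in range(kmax):
        w = w0 + k
        lo = np.maximum(pa, w * window)
        hi = np.minimum(pb, (w + 1) * window)
        ov[:, k] = np.maximum(hi - lo, 0.0)
        widx[:, k] = np.minimum(w, n_win - 1)

    mean_tab = cal.mean
    fgv_tab = cal.fgv_mean
    g0 = cal.log_rho_grid[0]
    dg = cal.log_rho_grid[1] - cal.log_rho_grid[0]
    n_grid = len(cal.log_rho_grid)

    def fit_window(db, robs, wt, fobs, wf, gother, ow, dsp):
        """Joint weighted SSE over r² and four-gamete responses, minimized
        over the window's rate by log-grid zoom."""
        lo, hi = 1e-6, rho_max
        best = lo
        for _ in range(3):
            xs = np.geomspace(lo, hi, 9)
            rho_eff = (gother[None, :] + xs[:, None] * ow[None, :]) / dsp[None, :]
            lr = np.log10(np.clip(rho_eff, 1e-8, None))
            x = np.clip((lr - g0) / dg, 0, n_grid - 1 - 1e-9)
            j = x.astype(int)
            f = x - j
            pred_r = mean_tab[db, j] * (1 - f) + mean_tab[db, j + 1] * f
            sse = ((pred_r - robs[None, :]) ** 2 * wt[None, :]).sum(axis=1)
            if fgv_tab is not None:
                pred_f = fgv_tab[db, j] * (1 - f) + fgv_tab[db, j + 1] * f
                sse += ((pred_f - fobs[None, :]) ** 2 * wf[None, :]).sum(axis=1)
            k = int(np.argmin(sse))
            best = xs[k]
            lo = xs[max(k - 1, 0)]
            hi = xs[min(k + 1, len(xs) - 1)]
        return float(best)

    def fgv_weights(db, rho):
        """Bernoulli inverse-variance weights for the FGV response."""
        p = cal.predict_fgv(db, rho)
        return 1.0 / np.maximum(p * (1 - p), 0.05)

    # initial per-window estimates: invert the calibrated surface on the
    # window's own pairs assuming a locally uniform rate
    est = np.full(n_win, np.nan)
    have = np.zeros(n_win, dtype=bool)
    zeros = np.zeros(0)
    for w in range(n_win):
        sel = w0 == w
        m = int(sel.sum())
        if m < min_pairs:
            continue
        dsp = d_span[sel]
        est[w] = fit_window(dbin[sel], r2[sel], np.ones(m),
                            fgv[sel], np.ones(m), np.zeros(m), dsp, dsp)
        have[w] = True
    if not have.any():
        raise ValueError("no window had enough informative pairs")
    est = np.where(np.isnan(est), np.nanmedian(est[have]), est)

    # pairs touching each window, with their overlap, precomputed once
    touch: list[np.ndarray] = [np.array([], dtype=np.int64)] * n_win
    overlaps: list[np.ndarray] = [zeros] * n_win
    parts: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for k in range(kmax):
        nz = np.flatnonzero(ov[:, k] > 0)
        ws = widx[nz, k]
        order = np.argsort(ws, kind="stable")
        ws_s, nz_s = ws[order], nz[order]
        ov_s = ov[nz_s, k].astype(float)
        bounds = np.searchsorted(ws_s, np.arange(n_win + 1))
        for w in range(n_win):
            if bounds[w + 1] > bounds[w]:
                parts.setdefault(w, []).append(
                    (nz_s[bounds[w]:bounds[w + 1]], ov_s[bounds[w]:bounds[w + 1]]))
    for w, lst in parts.items():
        t = np.concatenate([a for a, _ in lst])
        o = np.concatenate([b for _, b in lst])
        # a pair may touch the same window from one k only, so no dedup needed
        touch[w] = t
        overlaps[w] = o

    ones = np.ones(len(r2))
    for p in range(n_passes):
        gamma_full = (ov * est[widx]).sum(axis=1, dtype=np.float64)
        wts_rho = np.maximum(gamma_full / np.maximum(d_span, 1.0), 1e-8)
        wts = cal.weights(dbin, wts_rho)
        wfs = fgv_weights(dbin, wts_rho) if fgv_tab is not None else ones
        # alternate sweep direction so smearing is not directional
        order = range(n_win) if p % 2 == 0 else range(n_win - 1, -1, -1)
        for w in order:
            t = touch[w]
            if len(t) < min_pairs or not have[w]:
                continue
            ow = overlaps[w]
            gother = gamma_full[t] - est[w] * ow
            new = fit_window(dbin[t], r2[t], wts[t], fgv[t], wfs[t],
                             gother, ow, d_span[t])
            gamma_full[t] += (new - est[w]) * ow
            est[w] = new

    intervals = []
    for w in range(n_win):
        if have[w] and est[w] < 0.9 * rho_max:
            intervals.append((w * window, min((w + 1) * window, L), est[w]))
    if not intervals:
        raise ValueError("no window had enough informative pairs")
    return RhoLandscape.from_intervals(block.chromosome, intervals)
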