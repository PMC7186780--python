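"""End-to-end demonstration pipeline on synthetic data.

Chains every stage — simulate haplotypes under a known hotspot map, filter
sites, estimate the windowed ρ landscape, detect hotspots and score power
against the planted truth, classify a generated annotation and correlate it
with ρ, convert simulated crossovers to cM/Mb in ρ and diversity bins, and
compute the frequency of sex — writing all intermediate files plus a log to
a report directory. With a fixed seed the report is byte-identical across
runs.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .codiv import diversity_binned_co_rate, rho_binned_co_rate, theta_pi_windows
from .correlates import annotation_rho, annotation_tracts, classify_sites, gc_rho_correlation, rho_density_regression
from .filters import filter_vcf
from .haplotypes import HaplotypeBlock
from .hotspots import detect_hotspots, evaluate_power, regions_to_bed
from .landscape import chromosome_stats, summarize_windows, windows_to_landscape, write_rho_intervals
from .ld import apply_window_bias, calibrate_r2, calibrate_window_bias, decay_statistics, fit_ld_decay, pairwise_r2, windowed_rho
from .mutmat import load_printed_matrix
from .sexfreq import SexFrequencyInputs, frequency_of_sex, generations_to_days, realized_r
from .simulate import SimConfig, build_truth_map, generate_annotation, generate_crossovers, generate_genome_sequence, simulate_haplotypes

#: published scalar constants used for the built-in frequency-of-sex check
PUBLISHED = {
    "rho": 4.09e-3,       # genome-wide mean population recombination rate /bp
    "theta": 2.75e-2,     # silent-site diversity (2 Ne mu)
    "mu": 9.63e-10,       # mutations /bp /generation (MA lines)
    "r_cm_mb": 12.0,      # lab crossover rate, cM/Mb
    "ne": 1.4e7,          # effective population size
    "doublings_per_day": 2.5,
}


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the study's stated choices."""

    n_samples: int = 19
    seq_length: int = 1_000_000
    theta: float = 0.03
    background_rho: float = 0.001
    window: int = 2000
    flank: int = 100_000
    fold: float = 5.0
    min_hotspot_len: int = 2000
    gq_min: float = 30.0
    maf_min: float = 0.1
    n_boot: int = 1000
    n_offspring: int = 108
    r_cm_mb: float = 12.0
    co_bins: int = 50
    genic_fraction: float = 0.858
    diversity_window: int = 10_000
    min_silent: int = 500
    calibration_reps: int = 2
    seed: int = 0
    extra: dict = field(default_factory=dict)


def read_config(path) -> RunConfig:
    """Flat ``key = value`` text config; unknown keys go to ``extra``."""
    cfg = RunConfig()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected key = value")
        key, val = (s.strip() for s in line.split("=", 1))
        if hasattr(cfg, key) and key != "extra":
            cur = getattr(cfg, key)
            typ = type(cur)
            setattr(cfg, key, typ(float(val)) if typ in (int, float) else typ(val))
        else:
            cfg.extra[key] = val
    return cfg


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_demo(seed: int, outdir, config: RunConfig | None = None,
             log=print) -> dict:
    """Run the full synthetic analysis; returns the summary dict.

    Stage failures raise with the stage name prefixed; every output lands in
    ``outdir``.
    """
    cfg = config or RunConfig()
    cfg.seed = seed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(10)]
    summary: dict = {"seed": seed, "version": __version__}
    stage = "setup"
    try:
        stage = "simulate"
        sim = SimConfig(n_samples=cfg.n_samples, seq_length=cfg.seq_length,
                        theta=cfg.theta, background_rho=cfg.background_rho,
                        seed=seeds[0])
        truth = build_truth_map(sim)
        truth.to_tsv(out / "truth_map.tsv")
        block = simulate_haplotypes(sim, truth, load_printed_matrix(),
                                    out_vcf=out / "haplotypes.vcf")
        summary["n_sites_simulated"] = block.n_sites
        summary["pi_per_bp"] = block.pairwise_diversity()

        stage = "filter"
        counts = filter_vcf(out / "haplotypes.vcf", out / "filtered.vcf",
                            gq_min=cfg.gq_min, maf_min=cfg.maf_min)
        summary["filter_counts"] = counts.as_dict()
        fblock = HaplotypeBlock.read_vcf(out / "filtered.vcf")

        stage = "ld_decay"
        pr = pairwise_r2(fblock, max_dist=100_000, max_pairs=200_000, seed=seeds[1])
        model = fit_ld_decay(pr["d"], pr["r2"], fblock.n_samples)
        dstats = decay_statistics(model)
        summary["ld_decay"] = {
            "rho_hat": model.rho_hat,
            "half_decay_bp": dstats.half_decay_bp,
            "baseline_bp": dstats.baseline_bp,
            "baseline_r2": dstats.baseline_r2,
        }

        stage = "windowed_rho"
        log(f"[{stage}] calibrating the window estimator "
            f"({cfg.calibration_reps} reps per ladder point)")
        cal = calibrate_r2(n_samples=cfg.n_samples, theta=cfg.theta,
                           maf_min=cfg.maf_min, reps=cfg.calibration_reps,
                           seed=seeds[2])
        delta = calibrate_window_bias(cal, background_rho=cfg.background_rho,
                                      reps=2, seed=seeds[3],
                                      seq_length=min(250_000, cfg.seq_length),
                                      window=cfg.window)
        lands = apply_window_bias(
            windowed_rho(fblock, window=cfg.window, calibration=cal, seed=seeds[4]),
            delta)
        write_rho_intervals(lands, out / "rho_intervals.txt")
        windows = summarize_windows(lands, cfg.window)
        windows.to_csv(out / "rho_windows.tsv", sep="\t", index=False)
        cstats = chromosome_stats(lands)
        summary["rho"] = {
            "genome_mean": cstats.genome_mean,
            "window_bias_offset": delta,
        }

        stage = "hotspots"
        regions = detect_hotspots(windows, flank=cfg.flank, fold=cfg.fold,
                                  min_len=cfg.min_hotspot_len)
        regions_to_bed(regions, out / "hotspots.bed")
        power = evaluate_power(truth, regions)
        summary["hotspots"] = {
            "n_detected_regions": len(regions),
            "power": power.power,
            "power_by_fold": power.by_fold,
        }

        stage = "correlates"
        ann = generate_annotation(cfg.seq_length, genic_fraction=cfg.genic_fraction,
                                  seed=seeds[5], out_gff=out / "annotation.gff3")
        mask = classify_sites(out / "annotation.gff3", {block.chromosome: cfg.seq_length})
        rho_table = annotation_rho(mask, lands, n_boot=cfg.n_boot, seed=seeds[6])
        rho_table.to_csv(out / "annotation_rho.tsv", sep="\t", index=False)
        tracts = annotation_tracts(mask, lands, {block.chromosome: fblock.positions})
        reg = rho_density_regression(tracts)
        seq = generate_genome_sequence(cfg.seq_length, seed=seeds[7])
        gc_rho, gc_p, _ = gc_rho_correlation(seq, lands, window=cfg.window)
        summary["correlates"] = {
            "genic_fraction_realized": ann.genic_fraction,
            "regression_r_squared": reg.r_squared,
            "gc_rho_spearman": gc_rho,
            "gc_rho_p": gc_p,
        }

        stage = "crossovers"
        cos = generate_crossovers(truth, n_offspring=cfg.n_offspring,
                                  r_scale=cfg.r_cm_mb, seed=seeds[8])
        cos.write_tsv(out / "crossovers.tsv")
        co_rho = rho_binned_co_rate(lands, cos, n_bins=cfg.co_bins)
        co_rho.to_csv(out / "co_rate_by_rho.tsv", sep="\t", index=False)
        div = theta_pi_windows(block, mask.silent_mask(block.chromosome),
                               window=cfg.diversity_window, min_silent=cfg.min_silent)
        div.to_csv(out / "diversity_windows.tsv", sep="\t", index=False)
        co_div, co_fit = diversity_binned_co_rate(
            div, cos, n_bins=cfg.co_bins, min_bin_bp=cfg.seq_length / 5)
        co_div.to_csv(out / "co_rate_by_diversity.tsv", sep="\t", index=False)
        summary["crossovers"] = {
            "n_crossovers": len(cos),
            "diversity_fit_r_squared": co_fit.r_squared if co_fit else None,
        }

        stage = "sex_frequency"
        f_pub, gens_pub = frequency_of_sex(SexFrequencyInputs(
            rho=PUBLISHED["rho"], theta=PUBLISHED["theta"],
            r_cm_mb=PUBLISHED["r_cm_mb"], mu=PUBLISHED["mu"]))
        f_demo, gens_demo = frequency_of_sex(SexFrequencyInputs(
            rho=cstats.genome_mean, theta=cfg.theta,
            r_cm_mb=cfg.r_cm_mb, mu=PUBLISHED["mu"]))
        summary["sex_frequency"] = {
            "published_constants": {
                "f": f_pub,
                "generations_per_sex": gens_pub,
                "days_per_sex": generations_to_days(gens_pub,
                                                    PUBLISHED["doublings_per_day"]),
                "realized_r_cm_mb": realized_r(PUBLISHED["rho"], PUBLISHED["ne"]),
            },
            "demo_estimates": {"f": f_demo, "generations_per_sex": gens_demo},
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    _write_json(summary, out / "report.json")
    with open(out / "run.log", "w") as fh:
        fh.write(f"rhoscape {__version__}\n")
        fh.write(f"python {sys.version.split()[0]}; numpy {np.__version__}\n")
        fh.write(f"master seed {seed}; stage seeds {seeds}\n")
        fh.write("config:\n")
        for k, v in asdict(cfg).items():
            fh.write(f"  {k} = {v}\n")
    return summary
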