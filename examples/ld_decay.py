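"""Fit the LD decay curve to simulated haplotypes and summarize it.

Simulates 19 haploid genomes over 200 kb at diversity theta = 0.03 under a
uniform recombination map, computes pairwise r² within 25 kb, fits the
single-parameter decay expectation E(r² | Gamma = rho*d), and reports the
half-decay distance and the distance at which the curve flattens.
"""

from rhoscape import (
    SimConfig, build_truth_map, simulate_haplotypes,
    pairwise_r2, fit_ld_decay, decay_statistics,
)

TRUE_RHO = 0.004  # per bp

cfg = SimConfig(seq_length=200_000, background_rho=TRUE_RHO,
                hotspot_spec=(), seed=7)
block = simulate_haplotypes(cfg, build_truth_map(cfg))
block = block.filter_maf(0.1)

pairs = pairwise_r2(block, max_dist=25_000, max_pairs=150_000, seed=0)
model = fit_ld_decay(pairs["d"], pairs["r2"], block.n_samples)
stats = decay_statistics(model)

print(f"simulated rho            = {TRUE_RHO}")
print(f"fitted rho               = {model.rho_hat:.5f}  ({model.n_pairs} pairs)")
print(f"r² at d = 1 bp           = {stats.start_r2:.3f}")
print(f"half-decay distance      = {stats.half_decay_bp} bp")
print(f"baseline distance        = {stats.baseline_bp} bp (|slope| < 5e-6 per bp)")
print(f"r² at baseline           = {stats.baseline_r2:.3f}")
print()
print("Reading: r² starts near the finite-sample ceiling, halves within a")
print("few hundred bp at this rho, and levels off near 1/n (n = 19) once")
print("Gamma = rho*d is large.")
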