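"""Relate a recombination landscape to gene annotation.

Generates a gene-dense annotation (~86% genic, mostly sub-2-kb intergenic
tracts), paints a landscape in which intergenic sequence recombines at
three times the genic rate, classifies every bp from the GFF3, and
recovers the contrast with bootstrap confidence intervals plus a
hotspot-in-annotation enrichment test.
"""

import tempfile
from pathlib import Path

import numpy as np

from rhoscape import (
    RhoLandscape, annotation_rho, classify_sites, generate_annotation,
    enrichment_test, HotspotRegion,
)

L = 300_000
with tempfile.TemporaryDirectory() as tmp:
    gff = Path(tmp) / "genes.gff3"
    ann = generate_annotation(L, genic_fraction=0.858, seed=3, out_gff=gff)
    mask = classify_sites(gff, {"chr1": L})

print(f"realized genic fraction: {ann.genic_fraction:.3f}")
counts = mask.bp_counts()
print("bp per label:", {k: v for k, v in counts.items() if v})

# paint rho: 0.002 in genes, 0.006 intergenic
genic = mask.genic_mask("chr1")
rho = np.where(genic, 0.002, 0.006)
edges = np.flatnonzero(np.diff(rho)) + 1
starts = np.concatenate([[0], edges])
ends = np.concatenate([edges, [L]])
landscape = RhoLandscape.from_intervals(
    "chr1", np.column_stack([starts, ends, rho[starts]]))

table = annotation_rho(mask, landscape, n_boot=300, seed=0)
print(table[["category", "mean_rho", "ci_low", "ci_high"]].to_string(index=False))

# enrichment: put two fake hotspots inside intergenic sequence
ig = np.flatnonzero(~genic)
regions = [HotspotRegion("chr1", int(ig[100]), int(ig[100]) + 2000, 0.03, 0.005, 6.0),
           HotspotRegion("chr1", int(ig[-3000]), int(ig[-3000]) + 2000, 0.03, 0.005, 6.0)]
enr = enrichment_test(regions, ~genic, L)
print(f"hotspot x intergenic enrichment: OR = {enr.odds_ratio:.2f}, p = {enr.p_value:.3g}")
print()
print("Reading: the painted genic/intergenic rates are recovered exactly —")
print("the CIs collapse to zero width because rho is constant within each")
print("label — and hotspots placed in intergenic sequence give an odds")
print("ratio well above 1.")
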