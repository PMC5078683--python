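"""Relate SSR density to genes and transposable elements along a chromosome.

Builds a toy chromosome where SSRs and genes concentrate near the ends
while TEs fill the middle, computes 1 Mb window counts, and prints the
per-chromosome Pearson correlations: positive for SSR-gene, negative
for SSR-TE, the signature of repeats tracking gene-rich chromosome arms.
"""

import numpy as np

from palmsat import (
    AnnotationSet,
    SSRLocus,
    chromosome_correlations,
    classify_genic_context,
    context_proportions,
    window_densities,
)

rng = np.random.default_rng(5)
ann = AnnotationSet()
loci = []
length = 10_000_000
for w in range(10):
    near_end = w in (0, 1, 8, 9)
    base = w * 1_000_000
    for p in rng.integers(0, 999_000, rng.poisson(60 if near_end else 10)):
        loci.append(SSRLocus("chr1", base + int(p), base + int(p) + 12,
                             "ag", 6, "ag/ct"))
    for p in rng.integers(0, 999_000, rng.poisson(30 if near_end else 5)):
        ann.add_gene("chr1", base + int(p), base + int(p) + 2_000)
    for p in rng.integers(0, 999_000, rng.poisson(10 if near_end else 45)):
        ann.add_te("chr1", base + int(p), base + int(p) + 800)

windows = window_densities(loci, ann, {"chr1": length})
corr = chromosome_correlations(windows).iloc[0]
print(f"windows: {int(corr.n_windows)} x 1 Mb")
print(f"SSR density:  {corr.ssr_per_mb:.1f}/Mb")
print(f"gene density: {corr.gene_per_mb:.1f}/Mb")
print(f"TE density:   {corr.te_per_mb:.1f}/Mb")
print(f"r(SSR, gene) = {corr.r_ssr_gene:+.2f}")
print(f"r(SSR, TE)   = {corr.r_ssr_te:+.2f}")

contexts = [classify_genic_context(l, ann) for l in loci]
props = context_proportions(contexts)
print()
print(f"genic: {props['genic_pct']:.1f}%  intergenic: {props['intergenic_pct']:.1f}%")
print()
print("Positive SSR-gene and negative SSR-TE correlations mirror the")
print("pericentromere-poor, arm-rich distribution of plant microsatellites.")
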