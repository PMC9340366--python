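"""Linkage-disequilibrium decay: relatedness pruning, pairwise r² within
a distance window, 2 kb binning and mean r² at named distances.

The expectation of r² between two loci declines with the product 4*Ne*c
(effective size times recombination distance), so a small-Ne population
shows high background LD that decays slowly over tens of kb.
"""

from chipforge import synthdata
from chipforge.ldkit import (
    bin_ld,
    genomic_relatedness,
    ld_decay_summary,
    pairwise_r2,
    prune_related,
)

cfg = synthdata.SimulationConfig(
    n_chrom=1, chrom_length_bp=1_000_000, mutation_density=0.005,
    duplicated_fraction=0.0, effective_size=50, recomb_rate=1e-8,
    genotype_error_rate=0.0, seed=5,
)
haps = synthdata.simulate_haplotypes(cfg)
gmat = synthdata.sample_diploid_matrix(haps, 50, cfg)

R = genomic_relatedness(gmat)
kept = prune_related(R, gmat.samples, cutoff=0.12)
print(f"relatedness pruning at 0.12: {len(kept)}/{len(gmat.samples)} "
      f"samples retained (Ne=50 makes everyone related)")

pairs = pairwise_r2(gmat, max_dist=50_000, maf_min=0.05)
bins = bin_ld(pairs, bin_width=2000)
print(f"\n{len(pairs):,} SNP pairs binned into {len(bins)} x 2 kb bins")
summary = ld_decay_summary(bins, [1000, 4000, 10_000, 50_000])
for d, r2 in summary.items():
    print(f"  mean r2 at {d/1000:5.0f} kb : {r2:.3f}")
# With Ne=50 and c=1e-8 M/bp, 4*Ne*c*d is only 0.1 at 50 kb, so decay
# over this window is shallow; the drop becomes large near 1 Mb.
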