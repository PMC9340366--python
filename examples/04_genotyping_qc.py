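"""Post-genotyping validation of a panel: conversion categories, call
rates, Hardy-Weinberg exact testing and the MAF spectrum.
"""

import numpy as np

from chipforge import synthdata
from chipforge.genoqc import classify_conversion, maf_spectrum, qc_filter

cfg = synthdata.SimulationConfig(
    n_chrom=2, chrom_length_bp=500_000, mutation_density=0.004,
    duplicated_fraction=0.0, genotype_error_rate=0.002, missing_rate=0.01,
    seed=4,
)
haps = synthdata.simulate_haplotypes(cfg)
gmat = synthdata.sample_diploid_matrix(haps, 50, cfg, population="LB")

report = classify_conversion(gmat, snp_cr_min=0.97)
print(f"{gmat.n_snps} SNPs genotyped in {len(gmat.samples)} fish:")
for cat, frac in report.fractions.items():
    print(f"  {cat:<22s} {100 * frac:5.2f}%")

kept, ledger = qc_filter(gmat, cr_min=0.95, hwe_alpha=1e-7)
print(f"\nQC: kept {ledger['kept']} SNPs "
      f"({ledger['kept_polymorphic']} polymorphic), removed "
      f"{ledger['removed_call_rate']} on call rate, "
      f"{ledger['removed_hwe']} on HWE")

maf = gmat.maf()
maf = maf[~np.isnan(maf)]
edges = [0, 0.05, 0.15, 0.25, 0.35, 0.5]
counts = maf_spectrum(maf, edges)
print("\nMAF spectrum:")
for lo, hi, c in zip(edges, edges[1:], counts):
    print(f"  [{lo:.2f},{hi:.2f})  {c:5d}  ({100 * c / counts.sum():.1f}%)")
# PolyHighResolution = all three genotype clusters seen and call rate
# passes; NoMinorHom marks SNPs whose minor-allele homozygote was never
# observed (common at low MAF with 50 fish).
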