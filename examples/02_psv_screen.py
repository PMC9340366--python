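"""Screen out paralogous sequence variants (PSVs) using doubled-haploid
heterozygosity, with full attrition accounting.

DH fish carry two identical chromosome sets, so any site where two or
more DH lines are called heterozygous almost certainly sits in collapsed
duplicated sequence.  The replicate-concordance filter first drops sites
where resequenced copies of the same line disagree.
"""

from chipforge import synthdata
from chipforge.attrition import Ledger
from chipforge.popfilter import (
    dh_heterozygosity_filter,
    fully_genotyped_filter,
    replicate_concordance_filter,
)

cfg = synthdata.SimulationConfig(
    n_chrom=2, chrom_length_bp=150_000, mutation_density=0.004,
    duplicated_fraction=0.2, psv_het_rate=0.8, genotype_error_rate=0.001,
    seed=2,
)
ref = synthdata.simulate_reference(cfg)
haps = synthdata.simulate_haplotypes(cfg, ref)
dh = synthdata.sample_doubled_haploids(
    haps, ref, 12, cfg, replicate_map={"L1_rep": "L1", "L2_rep": "L2"}
)

ledger = Ledger()
step1 = replicate_concordance_filter(dh, ledger=ledger)
step2 = dh_heterozygosity_filter(step1, max_het=1, ledger=ledger)
step3 = fully_genotyped_filter(step2, ledger=ledger)
ledger.check()

dup_before = sum(ref.in_duplicated(r.chrom, r.pos) for r in step1.records)
dup_after = sum(ref.in_duplicated(r.chrom, r.pos) for r in step2.records)

print(ledger.to_frame().to_string(index=False))
print(f"\nduplicated-segment sites before het screen: {dup_before}")
print(f"duplicated-segment sites surviving it:      {dup_after}")
print(f"PSV removal: {100 * (1 - dup_after / max(dup_before, 1)):.1f}%")
# Nearly every site inside a duplicated segment is removed at max_het=1,
# while unique-sequence sites pass untouched.
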