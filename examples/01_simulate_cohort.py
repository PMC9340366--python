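"""Simulate a complete study cohort: a repeat-rich reference genome, a
Wright-Fisher population of haplotypes, fully homozygous doubled-haploid
(DH) lines with PSV artifacts, and a diploid population — then write
them in the standard interchange formats (FASTA/BED/VCF/TSV).

The duplicated segments make some loci behave like paralogous sequence
variants: in DH lines, which should be homozygous everywhere, those loci
show heterozygous calls — exactly the signature the screening filters
look for downstream.
"""

import os
import tempfile

from chipforge import synthdata
from chipforge.variantstore import write_vcf

cfg = synthdata.SimulationConfig(
    n_chrom=2, chrom_length_bp=200_000, mutation_density=0.004,
    duplicated_fraction=0.1, psv_het_rate=0.8, effective_size=50,
    seed=1,
)
ref = synthdata.simulate_reference(cfg)
haps = synthdata.simulate_haplotypes(cfg, ref)
dh = synthdata.sample_doubled_haploids(
    haps, ref, n_lines=12, config=cfg, replicate_map={"L1_rep": "L1"}
)
diploids = synthdata.sample_diploids(haps, 50, cfg)

out = tempfile.mkdtemp(prefix="chipforge_cohort_")
synthdata.write_fasta(ref.sequences, os.path.join(out, "reference.fa"))
synthdata.write_bed(ref.duplicated, os.path.join(out, "duplicated.bed"))
write_vcf(dh, os.path.join(out, "dh.vcf"), contig_lengths=ref.chrom_lengths())
write_vcf(diploids, os.path.join(out, "diploids.vcf"),
          contig_lengths=ref.chrom_lengths())
dh.roster.to_tsv(os.path.join(out, "samples.tsv"))

dup_bp = sum(e - s for _, s, e in ref.duplicated)
print(f"reference: {len(ref.sequences)} chromosomes x "
      f"{cfg.chrom_length_bp:,} bp, {dup_bp:,} bp in duplicated segments")
print(f"haplotypes: {haps.n_haplotypes} x {haps.n_sites()} segregating sites")
print(f"DH call set: {len(dh)} sites x {len(dh.samples)} samples "
      f"(12 lines, 1 replicated)")
print(f"diploid call set: {len(diploids)} sites x 50 individuals")
print(f"written to {out}")
# Each site is a candidate marker; the duplicated-segment BED tells us
# which ones are PSV-prone and should be caught by the DH het screen.
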