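# chipforge

Design and validate high-density SNP genotyping arrays for species with
messy, repeat-rich genomes — built around the cascade used for salmonid
(rainbow trout-style) array development, where a recent whole-genome
duplication makes paralogous sequence variants (PSVs) the main enemy of
reliable markers.

`chipforge` is a Python library (plus a thin `chipforge` CLI) covering the
whole pipeline:

* **synthdata** — seeded synthetic cohorts: a reference genome with
  near-identical duplicated segments, a forward Wright-Fisher population
  of haplotypes with recombination and recurrent mutation, fully
  homozygous doubled-haploid (DH) lines whose duplicated-segment sites
  read as heterozygous artifacts, replicated samples, and random-mating
  diploid populations. VCF/FASTA/BED/TSV are the interchange formats, so
  synthetic and real data follow one code path.
* **variantstore** — VCF data model, merging with allele reconciliation
  (shared positions may gain alternate alleles), multi-caller
  intersection, and GATK-style INFO/QUAL hard-filter expressions
  (`"QD < 2.0 || MQ < 40.0 || ..."`).
* **popfilter** — MAF computation and floors, bi-allelism and chromosome
  allow-lists, replicate-concordance filtering across resequenced
  isogenic lines, and the PSV screen: drop sites heterozygous in more
  than `max_het` doubled haploids.
* **probedesign** — spacing against the full variant catalogue (≥ 50 bp
  to the nearest identified SNP), 50 bp flank extraction, N-run
  trimming, 35-mer probe uniqueness (exact or scored scan, both
  strands), A/T–C/G ambiguity screening, MAF-based preselection rounds,
  per-100 kb density balancing, legacy-marker retention and panel
  assembly (TSV + probe FASTA with `[ref/alt]` deflines).
* **genoqc** — call rates, the four conversion categories
  (PolyHighResolution / MonoHighResolution / NoMinorHom / Failed), the
  exact conditional Hardy-Weinberg test, QC filtering with two-way
  removal accounting, and MAF spectra.
* **maptools** — probe remapping to a second assembly with
  best-hit-edge uniqueness (internal exhaustive aligner or ingested
  blast-style tabular hits), inter-marker gap statistics and per-window
  marker density.
* **ldkit** — genomic relationship matrix, greedy relatedness pruning at
  a cutoff, pairwise r² on unphased dosages within a distance window,
  2 kb distance binning and LD-decay summaries.

Every filtering stage reports attrition through a shared `Ledger`, which
asserts that removals plus survivors reconcile exactly.

## The statistics at the core

* **PSV screen.** A doubled-haploid individual carries two identical
  chromosome sets; at a true SNP its genotype must be homozygous.  A
  site heterozygous in ≥ 2 DH lines almost certainly collapses two
  paralogous loci: with per-site artifact probability q and L lines, the
  chance a PSV escapes is P(#het ≤ 1) = (1−q)^L + Lq(1−q)^(L−1) — below
  2 × 10⁻³ already at q = 0.8, L = 6.
* **HWE exact test.** Conditional on the allele counts, the heterozygote
  count n_Aa has probability
  P(n_Aa | n, n_a) ∝ n! · 2^{n_Aa} / (n_AA! n_Aa! n_aa!) ÷ C(2n, n_a);
  the p-value sums all configurations no more probable than the observed
  one (plain exact p, ties included, no mid-p).
* **LD decay.** r² is the squared Pearson correlation of allele dosages;
  its expectation declines with C = 4·Ne·c (effective size × Morgans
  between loci), from ≈ 0.45 in a sample at full linkage toward 1/C at
  large C. Pairs are binned in 2 kb units, right-closed.

## Worked example

`examples/` holds one short script per capability. The PSV screen
(`python examples/02_psv_screen.py`) simulates 12 DH lines (two of them
replicated) on a genome with 20% duplicated sequence and prints:

```
                       stage  n_in  n_out  removed
       replicate_concordance   407    407        0
dh_heterozygosity[max_het=1]   407    324       83
             fully_genotyped   324    324        0

duplicated-segment sites before het screen: 83
duplicated-segment sites surviving it:      0
PSV removal: 100.0%
```

All 83 sites inside duplicated segments are flagged by DH
heterozygosity and removed; no unique-sequence site is lost.  The LD
example (`python examples/05_ld_decay.py`) prunes relatives at
relatedness 0.12, computes ~23,000 pairwise r² values on one 1 Mb
chromosome (Ne = 50, c = 1e-8 M/bp) and reports the shallow decay
expected when 4·Ne·c·d ≤ 0.1:

```
  mean r2 at     1 kb : 0.221
  mean r2 at     4 kb : 0.216
  mean r2 at    10 kb : 0.234
  mean r2 at    50 kb : 0.198
```

The design cascade (`python examples/03_design_panel.py`) prints the
full attrition table from a 622-SNP catalogue down to a 131-probe panel
(spacing, MAF ≥ 10%, probe unicity, ambiguity, density balancing).

## CLI

```bash
chipforge simulate --config sim.yaml --out cohort/   # FASTA+BED+VCFs+roster
chipforge design --vcf cohort/diploids.vcf --ref cohort/reference.fa \
                 --config design.yaml --out panel/   # panel TSV/FASTA
```

See `docs/methods.md` for the models, conventions and limitations.
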