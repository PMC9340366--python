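# Methods

This note records the models behind `chipforge`, the conventions every
filter follows, the parameters that matter, and what the synthetic
cohorts do and do not emulate.

## Synthetic cohorts (`synthdata`)

### Reference genome and duplicated segments

Each chromosome is an i.i.d. random sequence over {A,C,G,T}. Duplicated
segments emulate the residual tetraploidy of salmonid-like genomes:
2 kb donor windows from the left half of a chromosome are copied
verbatim into non-overlapping slots in the right half until
`duplicated_fraction` of the chromosome is covered (± one segment of
rounding). The BED annotation lists the copy segments (0-based,
half-open). Copies are exact, so any 35-mer probe anchored inside one is
guaranteed non-unique — the property the probe-uniqueness tests rely on.
`duplicated_fraction >= 0.5` is rejected because the donor/copy layout
becomes impossible.

### Wright-Fisher haplotypes

A population of 2·Ne haplotypes per chromosome evolves forward in time:

* candidate sites scattered at `mutation_density` per bp;
* standing variation initialised from the neutral site-frequency
  spectrum (derived-allele count k with probability ∝ 1/k);
* each generation, every offspring haplotype recombines the two
  haplotypes of a random parent (crossovers Poisson with mean
  c × span, breakpoints uniform), then every (haplotype, site) allele
  flips with probability `site_theta`/(4·Ne) — symmetric recurrent
  mutation that maintains variation at mutation–drift balance;
* burn-in of 4·Ne generations; only still-segregating sites are
  returned (an error suggests raising `mutation_density`).

Without recurrent mutation a population of this size nearly coalesces
within the burn-in and r² degenerates to ≈ 1 at all distances;
`site_theta = 0.08` (default) was calibrated once so the equilibrium
r²-versus-distance profile matches coalescent simulation (msprime) at
the same Ne and c across 0–2 kb, 48–50 kb, 0.9–1 Mb and 1.8–2 Mb bins.
One test keeps msprime as an independent cross-check of the decay
ordering. Chromosomes are simulated independently, which is exact for
neutral random mating.

Defaults (`SimulationConfig`): Ne = 50 (a small commercial line),
c = 1e-8 Morgans/bp (≈ 1 cM/Mb, the magnitude reported for trout-like
genomes), mutation_density = 0.002/bp, duplicated_fraction = 0.10,
psv_het_rate = 0.8, genotype_error_rate = 1e-3, missing_rate = 0.
Determinism: (config, seed) fixes every output byte; each operation
draws from a named RNG substream of the master seed, so adding an
operation never perturbs the others.

### Call-set sampling

*Doubled haploids.* Each line doubles one distinct haplotype: genotypes
a/a everywhere, except that duplicated-segment sites read 0/1 with
probability `psv_het_rate` (PSV artifacts are modeled at genotype level
— the pipeline only ever sees genotypes, not read alignments). Every
sample of a line — primary or replicate — receives independent errors
(an errored call moves to one of the other two genotype classes), so two
replicates disagree at ≈ 2e(1−e) of sites. Replicates get lower depth
rank than the primary sample, which the concordance filter uses for
deduplication. Allele strings are taken from the reference base with a
random alternate (its own substream); without a reference a fixed A>G is
used.

*Diploids.* Individuals pair haplotypes at random without replacement
(never a haplotype with itself), with missingness and errors applied
per genotype. `sample_diploids` emits a VCF-ready call set;
`sample_diploid_matrix` produces the dosage matrix directly for
QC-scale work (100k+ sites).

What the generator does **not** emulate: read-level artifacts (mapping
quality, allele balance, coverage), genotype-calling uncertainty,
population structure and admixture, selection, sex chromosomes, indels
and multi-allelic sites, and divergence between duplicated copies
(copies are exact). Passing tests therefore demonstrate the correctness
of the filtering logic and the qualitative population-genetic behaviour,
not calibrated performance on real resequencing data.

## Conventions and numerical choices

* Coordinates: VCF is 1-based inclusive; all internal interval
  arithmetic (BED, windows) is 0-based half-open. Window tilings anchor
  at coordinate 0.
* MAF: computed over called alleles; the keep rule is MAF ≥ floor
  (boundary kept). Zero called alleles is "undefined", signalled
  distinctly from 0.0, and such sites fail cleaning filters.
* Half-missing genotypes (`./1`) count as missing.
* Replicate discordance: a line with one replicate missing at a site is
  not discordant — missingness is not evidence of inconsistency.
* Merging: at a shared (chrom, pos, ref) the alt lists concatenate
  (first input's order, then novel alleles) and genotype indices are
  remapped by allele string, never positionally. A ref-allele conflict
  keeps both records tagged `FILTER=REF_CONFLICT`, excluded from
  preselection.
* INFO hard filters: a record lacking a referenced key is retained for
  that predicate (the convention of the caller whose expressions the
  filters mirror).
* Spacing: nearest-neighbour distance is measured against the full
  input catalogue, not the surviving set — a variant 40 bp from an
  already-removed variant still fails, because the neighbouring
  polymorphism still corrupts the probe.
* Flank trimming at runs of > 3 N keeps the variant-proximal segment
  (probes anchor at the variant); keep requires the shorter trimmed
  flank ≥ 20 bp and the longer one at the full 50 bp.
* Probe uniqueness: default is an exact scan of the variant-proximal
  35-mer and its reverse complement over the whole reference
  (deterministic, version-free); the scored mode (match +1, mismatch −1,
  ungapped, co-optimal margin 0) approximates default nucleotide-blast
  behaviour for near-duplicates.
* Density balancing: tiled 100 kb windows; windows holding **more than**
  30 candidates keep only candidates with best-population MAF ≥ 0.15.
  No quota beyond the MAF floor (the rule is a filter, not a cap), so
  the operation is idempotent.
* Conversion categories are assigned from dosages only (cluster
  geometry is not available): Failed = call rate below threshold;
  MonoHighResolution = at most one allele observed; NoMinorHom =
  polymorphic with the minor-allele homozygote class absent (includes
  the all-heterozygote edge case); PolyHighResolution = polymorphic
  with the minor homozygote observed. The usual "all three genotype
  clusters present" description is a subset of the last category;
  defining it this way makes the four categories provably exhaustive
  (e.g. for the {0,2}-only pattern). "Failed" collapses every
  non-call-rate cluster failure of real array software.
* HWE: plain exact conditional p (no mid-p); configurations with
  probability equal to the observed one (within 1e-12 relative) are
  included. Monomorphic sites return p = 1. Log-gamma arithmetic with a
  normalisation guard; the test suite checks every genotype triple up
  to n = 50 against an exact-rational enumeration oracle.
* QC removal precedence: call rate before HWE, so the two removal
  ledgers are disjoint and reconcile exactly. "Polymorphic" for
  reporting means MAF > 0.001.
* r²: squared Pearson correlation of unphased dosages over
  pairwise-complete samples (the statistic genotype-based LD tooling
  reports), never EM-phased haplotype frequencies. Zero-variance pairs
  are skipped with a reason. Pair selection: same chromosome, distance
  ≤ 1,001 kb, at most 50,000 intervening SNPs, MAF ≥ 0.05.
* LD bins are right-closed 2 kb units ((0,2000], (2000,4000], …); a
  pair at exactly 2,000 bp falls in the first bin. Decay summaries
  report the mean of the bin containing the query distance.
* GRM: entry(j,k) = mean over SNPs of (x_j−2p)(x_k−2p)/(2p(1−p)), MAF
  ≥ 0.05, pairwise-complete missing handling. With p estimated from the
  cohort itself the off-diagonal carries the standard −1/(n−1)
  small-sample bias (tested explicitly); external frequencies can be
  supplied. Relatedness pruning is greedy — repeatedly remove the
  sample in the most above-cutoff pairs, ties broken by removing the
  lexicographically larger id — a deterministic replacement for the
  unstated iteration order of the usual rel-cutoff implementations.
* Probe remapping uniqueness uses best-hit-edge semantics: unique iff
  the runner-up score is below best × (1 − score_edge), after
  discarding hits under the identity floor (0.95). Unplaced and
  ambiguous probes are reported separately. End-of-chromosome gaps
  enter gap statistics only when chromosome sizes are supplied.

## Design choices where the design was open

* Forward Wright-Fisher rather than coalescent simulation: the PSV and
  genotype-error machinery needs explicit individuals and meioses, and
  equilibrium LD under the 4·Ne·c relationship is reached by burn-in.
  msprime remains in the test suite as the independent oracle, not the
  implementation.
* PSV placement within duplicated segments is uniform (artifact
  probability is constant across a segment); real homology is
  concentrated on particular chromosome arms, which only affects where
  PSVs sit, not how the screen treats them.
* The density rule's "regions" are tiled, not sliding, windows —
  deterministic and matching the per-100 kb phrasing.
* Sample-size correction 1/(2n) for r² is applied only inside
  parameter-recovery tests; reported r² values are uncorrected, as LD
  tooling reports them.

## Problem sizes

The test-suite and acceptance-script cohorts are desk-scale by choice:
catalogues of 10²–10⁴ SNPs, genomes of 0.1–2 Mb, 12 DH lines, 50–100
diploids, 20 Wright-Fisher replicates for LD averages, and 100,000 SNPs
for the HWE type-I check. These sizes make every stochastic assertion
tight (binomial/normal bounds are stated in the tests) while the whole
suite runs in well under a minute of compute.

## Known limitations

* The exhaustive aligner is quadratic; it is meant for ≤ a few Mb of
  reference. Real remapping jobs should ingest external tabular hits
  through the provided adapter.
* Conversion categories cannot see cluster-geometry failures
  (off-target variants, cross-hybridisation) that array software would
  flag; such SNPs land in whichever dosage-level category they imitate.
* The equilibrium difference in mean r² between 0–2 kb and 48–50 kb at
  Ne = 50, c = 1e-8 is small (≈ 0.016); detecting it requires the
  pooled-pair sizes the tests use (thousands of pairs per bin over 20
  replicates).
* The greedy relatedness pruner guarantees a valid (no violating pair)
  set, not a maximum one; on small random instances it is within one
  sample of the brute-force optimum (tested).
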