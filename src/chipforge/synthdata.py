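"""Synthetic cohorts with the statistical structure the design pipeline
assumes.

This module generates, from a single seeded configuration:

* a reference genome containing near-identical duplicated segments (the
  salmonid-style residual tetraploidy that produces paralogous sequence
  variants, PSVs);
* haplotypes from a forward-in-time Wright-Fisher population of 2·Ne
  chromosomes with crossover recombination, so that equilibrium linkage
  disequilibrium follows the classical dependence of E[r²] on 4·Ne·c;
* doubled-haploid (DH) call sets — fully homozygous lines, optionally with
  replicate samples, where sites inside duplicated segments yield
  heterozygous PSV artifacts with a configurable probability;
* diploid population call sets formed by random pairing of haplotypes.

Everything is deterministic given (config, seed); every operation draws
from its own named substream of the master seed, so adding an operation
never perturbs the others.  VCF v4.2 is the sole interchange format with
the rest of the pipeline.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .popfilter import DIPLOID, DOUBLED_HAPLOID, RosterEntry, SampleRoster
from .variantstore import CallSet, VariantRecord

__all__ = [
    "SimulationConfig",
    "HaplotypeSet",
    "Reference",
    "simulate_reference",
    "simulate_haplotypes",
    "sample_doubled_haploids",
    "sample_diploids",
    "sample_diploid_matrix",
    "write_fasta",
    "write_bed",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: length of each duplicated segment (bp); longer than any probe so that
#: flank-uniqueness checks inside a copy must fail.
DUP_SEGMENT_LEN = 2000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a desk-scale version of a salmonid resequencing
    design: a repeat-rich genome (duplicated_fraction), DH lines whose
    PSV sites read as heterozygous most of the time (psv_het_rate), a
    small effective population size typical of a commercial line, and the
    rainbow-trout-scale recombination rate of ~1e-8 Morgans/bp (~1 cM/Mb).
    """

    n_chrom: int = 2
    chrom_length_bp: int = 500_000
    mutation_density: float = 0.002  # expected segregating-site seeds per bp
    duplicated_fraction: float = 0.10
    psv_het_rate: float = 0.8
    effective_size: int = 50  # Ne
    recomb_rate: float = 1e-8  # Morgans per bp
    genotype_error_rate: float = 0.001
    missing_rate: float = 0.0
    site_theta: float = 0.08  # 4*Ne*mu per candidate site (recurrent mutation)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutation_density", "duplicated_fraction", "psv_het_rate",
                     "genotype_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.duplicated_fraction >= 0.5:
            raise ValueError(
                "duplicated_fraction >= 0.5: donor/copy layout impossible"
            )
        if self.effective_size < 2:
            raise ValueError("effective_size must be >= 2")
        if self.n_chrom < 1 or self.chrom_length_bp < 1:
            raise ValueError("genome dimensions must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if self.site_theta < 0:
            raise ValueError("site_theta must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream: independent generator per operation."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        )


@dataclass
class Reference:
    """In-memory reference genome with duplicated-segment annotation.

    ``duplicated`` holds 0-based half-open (chrom, start, end) intervals of
    the *copy* segments (the regions whose sequence exists elsewhere too).
    """

    sequences: dict[str, str]
    duplicated: list[tuple[str, int, int]] = field(default_factory=list)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def in_duplicated(self, chrom: str, pos: int) -> bool:
        """pos is 1-based."""
        z = pos - 1
        return any(c == chrom and s <= z < e for c, s, e in self.duplicated)


@dataclass
class HaplotypeSet:
    """Binary allele matrices (haplotype x site) with sorted 1-based
    positions, one block per chromosome."""

    positions: dict[str, np.ndarray]
    haplotypes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for c, pos in self.positions.items():
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
            h = self.haplotypes[c]
            if h.shape[1] != len(pos):
                raise ValueError(f"haplotype/position shape mismatch on {c}")
            if not np.isin(h, (0, 1)).all():
                raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return next(iter(self.haplotypes.values())).shape[0]

    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig) -> Reference:
    """Random genome over {A,C,G,T} with exact duplicated-segment copies.

    Donor segments are drawn from the left half of each chromosome and
    copied (verbatim) into non-overlapping slots in the right half; the
    annotation lists the copy segments and covers duplicated_fraction of
    each chromosome up to segment-size rounding.
    """
    rng = config.rng("reference")
    L = config.chrom_length_bp
    seqs: dict[str, str] = {}
    dup: list[tuple[str, int, int]] = []
    seg = min(DUP_SEGMENT_LEN, max(1, L // 10))
    n_seg = int(round(config.duplicated_fraction * L / seg))
    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        arr = _BASES[rng.integers(0, 4, size=L)]
        if n_seg:
            half = L // 2
            # non-overlapping copy slots in the right half
            slots = np.arange(half, L - seg + 1, seg)
            if len(slots) < n_seg:
                raise ValueError(
                    "duplicated_fraction too high for segment layout"
                )
            copy_starts = np.sort(rng.choice(slots, size=n_seg, replace=False))
            donor_starts = rng.integers(0, half - seg, size=n_seg)
            for d0, c0 in zip(donor_starts, copy_starts):
                arr[c0:c0 + seg] = arr[d0:d0 + seg]
                dup.append((chrom, int(c0), int(c0 + seg)))
        seqs[chrom] = arr.tobytes().decode()
    return Reference(sequences=seqs, duplicated=dup)


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(intervals: Sequence[tuple[str, int, int]], path: str) -> None:
    """0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Wright-Fisher haplotypes
# ---------------------------------------------------------------------------

def simulate_haplotypes(config: SimulationConfig,
                        reference: Reference | None = None) -> HaplotypeSet:
    """Forward Wright-Fisher population of 2·Ne haplotypes per chromosome.

    Candidate sites are scattered at mutation_density per bp; standing
    variation is initialised from the neutral site-frequency spectrum
    (initial derived-allele count k drawn with probability proportional
    to 1/k) and the population then evolves for 4·Ne generations of
    random mating with crossover recombination at ``recomb_rate``
    Morgans/bp and symmetric recurrent mutation at ``site_theta``/(4·Ne)
    per site per generation, so variation is maintained at
    mutation-drift balance.  The default ``site_theta`` was calibrated
    once so the equilibrium r²-versus-distance profile matches
    coalescent expectations for the same Ne and c.  Only sites still
    segregating after burn-in are returned.

    Chromosomes are simulated independently (valid for neutral random
    mating).  Raises if no site segregates — increase ``mutation_density``.
    """
    if config.mutation_density <= 0:
        raise ValueError(
            "mutation_density must be > 0 to obtain segregating sites"
        )
    rng = config.rng("haplotypes")
    n_hap = 2 * config.effective_size
    L = config.chrom_length_bp
    generations = 4 * config.effective_size
    chroms = (
        list(reference.sequences) if reference is not None
        else [f"chr{i + 1}" for i in range(config.n_chrom)]
    )
    positions: dict[str, np.ndarray] = {}
    haplotypes: dict[str, np.ndarray] = {}
    for chrom in chroms:
        m = rng.poisson(config.mutation_density * L)
        m = max(m, 1)
        pos = np.sort(rng.choice(L, size=min(m, L), replace=False)) + 1
        M = len(pos)
        # neutral SFS init: minor count k ~ 1/k over 1..n_hap-1
        ks = np.arange(1, n_hap)
        k = rng.choice(ks, size=M, p=(1 / ks) / np.sum(1 / ks))
        H = np.zeros((n_hap, M), dtype=np.uint8)
        for j in range(M):
            carriers = rng.choice(n_hap, size=k[j], replace=False)
            H[carriers, j] = 1
        mu = config.site_theta / (4 * config.effective_size)
        H = _evolve(H, pos, config.recomb_rate, mu, generations, rng)
        seg = (H.sum(axis=0) > 0) & (H.sum(axis=0) < n_hap)
        positions[chrom] = pos[seg]
        haplotypes[chrom] = H[:, seg]
    if sum(len(p) for p in positions.values()) == 0:
        raise RuntimeError(
            "no segregating sites after burn-in; increase mutation_density"
        )
    return HaplotypeSet(positions=positions, haplotypes=haplotypes)


def _evolve(H: np.ndarray, pos: np.ndarray, c: float, mu: float,
            generations: int, rng: np.random.Generator) -> np.ndarray:
    """One chromosome of Wright-Fisher evolution with crossovers and
    symmetric recurrent mutation.

    Each offspring haplotype is a recombinant of the two haplotypes of a
    randomly chosen parent; crossover counts per meiosis are Poisson with
    mean c · chromosome-span, breakpoints uniform on the span; each
    (haplotype, site) allele then flips with probability mu.
    """
    n_hap, M = H.shape
    n_ind = n_hap // 2
    span = float(pos[-1] - pos[0] + 1) if M else 0.0
    mean_xo = c * span
    for _ in range(generations):
        parents = rng.integers(0, n_ind, size=n_hap)
        which = rng.integers(0, 2, size=n_hap)
        new = H[2 * parents + which].copy()
        n_xo = rng.poisson(mean_xo, size=n_hap)
        for i in np.nonzero(n_xo)[0]:
            bp = np.sort(rng.uniform(pos[0], pos[-1] + 1, size=n_xo[i]))
            # alternate source haplotype at each breakpoint
            take_other = (np.searchsorted(bp, pos, side="right") % 2) == 1
            other = H[2 * parents[i] + (1 - which[i])]
            new[i, take_other] = other[take_other]
        n_flip = rng.poisson(mu * n_hap * M)
        if n_flip:
            new[rng.integers(0, n_hap, size=n_flip),
                rng.integers(0, M, size=n_flip)] ^= 1
        H = new
    return H


# ---------------------------------------------------------------------------
# call-set sampling
# ---------------------------------------------------------------------------

def _allele_table(haps: HaplotypeSet, reference: Reference | None,
                  config: SimulationConfig) -> dict[str, list[tuple[str, str]]]:
    """Per-site (ref, alt) allele strings.

    With a reference genome, ref is the actual base at the position and
    the alt is drawn uniformly among the other three bases (own RNG
    substream, so allele identity never perturbs genotype sampling);
    without one, a fixed A>G substitution is used.
    """
    rng = config.rng("alleles")
    table: dict[str, list[tuple[str, str]]] = {}
    for chrom, pos in haps.positions.items():
        if reference is None or chrom not in reference.sequences:
            table[chrom] = [("A", "G")] * len(pos)
            continue
        seq = reference.sequences[chrom]
        pairs = []
        for p in pos:
            ref_base = seq[int(p) - 1]
            others = [b for b in "ACGT" if b != ref_base]
            pairs.append((ref_base, others[rng.integers(0, 3)]))
        table[chrom] = pairs
    return table


def _apply_genotype_errors(gt: tuple[int, int], rng: np.random.Generator,
                           rate: float) -> tuple[int, int]:
    if rate > 0 and rng.random() < rate:
        current = tuple(sorted(gt))
        options = [g for g in ((0, 0), (0, 1), (1, 1)) if g != current]
        return options[rng.integers(0, len(options))]
    return gt


def sample_doubled_haploids(haps: HaplotypeSet,
                            reference: Reference | None,
                            n_lines: int,
                            config: SimulationConfig,
                            replicate_map: Mapping[str, str] | None = None,
                            population: str = "DH",
                            ) -> CallSet:
    """Call set of fully homozygous DH lines with PSV artifacts.

    Each line doubles one haplotype: genotype a/a everywhere, except that
    sites falling inside a duplicated segment of ``reference`` read as
    heterozygous with probability ``psv_het_rate`` (the PSV signature) and
    random genotype errors occur at ``genotype_error_rate``.  Replicate
    samples (``replicate_map``: extra sample id -> line id, lines named
    ``L1..Ln``) copy their line's genotypes and then receive independent
    errors; the replicate gets a lower depth rank than the primary sample.
    """
    if n_lines > haps.n_haplotypes:
        raise ValueError(
            f"n_lines={n_lines} exceeds {haps.n_haplotypes} haplotypes"
        )
    replicate_map = dict(replicate_map or {})
    line_ids = [f"L{i + 1}" for i in range(n_lines)]
    for rep_sample, line in replicate_map.items():
        if line not in line_ids:
            raise KeyError(f"replicate {rep_sample!r} references unknown line {line!r}")

    rng = config.rng("doubled_haploids")
    hap_choice = rng.choice(haps.n_haplotypes, size=n_lines, replace=False)

    samples = list(line_ids) + list(replicate_map)
    entries: dict[str, RosterEntry] = {}
    for li, line in enumerate(line_ids):
        replicated = line in replicate_map.values()
        entries[line] = RosterEntry(
            population=population, role=DOUBLED_HAPLOID, line_id=line,
            replicate_group=line if replicated else None, depth_rank=2,
        )
    for rep_sample, line in replicate_map.items():
        entries[rep_sample] = RosterEntry(
            population=population, role=DOUBLED_HAPLOID, line_id=line,
            replicate_group=line, depth_rank=1,
        )
    roster = SampleRoster(entries=entries)

    alleles = _allele_table(haps, reference, config)
    records: list[VariantRecord] = []
    for chrom in haps.positions:
        pos = haps.positions[chrom]
        H = haps.haplotypes[chrom]
        in_dup = (
            np.array([reference.in_duplicated(chrom, int(p)) for p in pos])
            if reference is not None and reference.duplicated
            else np.zeros(len(pos), dtype=bool)
        )
        for j, p in enumerate(pos):
            # a line's underlying genotype (PSV state included); each
            # sample of the line — primary or replicate — then receives
            # its own independent genotyping errors
            base_gts: dict[str, tuple[int, int]] = {}
            for li, line in enumerate(line_ids):
                a = int(H[hap_choice[li], j])
                gt: tuple[int, int] = (a, a)
                if in_dup[j] and rng.random() < config.psv_het_rate:
                    gt = (0, 1)
                base_gts[line] = gt
            gts: list[tuple[int, int]] = [
                _apply_genotype_errors(base_gts[s], rng,
                                       config.genotype_error_rate)
                for s in line_ids
            ]
            for rep_sample, line in replicate_map.items():
                gts.append(
                    _apply_genotype_errors(base_gts[line], rng,
                                           config.genotype_error_rate)
                )
            ref_b, alt_b = alleles[chrom][j]
            records.append(
                VariantRecord(chrom=chrom, pos=int(p), ref=ref_b,
                              alts=(alt_b,), genotypes=list(gts))
            )
    return CallSet(records=records, samples=samples, roster=roster,
                   provenance={population: "synthetic doubled haploids"})


def sample_diploid_matrix(haps: HaplotypeSet, n_ind: int,
                          config: SimulationConfig,
                          population: str = "POP"):
    """Random-mating diploid genotypes as a dosage matrix (no VCF
    round-trip) — the QC-scale companion of :func:`sample_diploids`.

    Same pairing, missingness and error model, vectorised for large site
    counts; returns a :class:`chipforge.genoqc.GenotypeMatrix`.
    """
    from .genoqc import GenotypeMatrix

    if 2 * n_ind > haps.n_haplotypes:
        raise ValueError(
            f"n_ind={n_ind} needs {2 * n_ind} haplotypes, "
            f"have {haps.n_haplotypes}"
        )
    rng = config.rng("diploids")
    perm = rng.permutation(haps.n_haplotypes)[: 2 * n_ind]
    pairs = perm.reshape(n_ind, 2)
    samples = [f"{population}_{i + 1:03d}" for i in range(n_ind)]
    blocks = []
    keys: list[tuple] = []
    for chrom in haps.positions:
        H = haps.haplotypes[chrom]
        d = (H[pairs[:, 0]] + H[pairs[:, 1]]).astype(np.int8)
        if config.genotype_error_rate > 0:
            err = rng.random(d.shape) < config.genotype_error_rate
            # uniform among the two other genotype classes
            shift = rng.integers(1, 3, size=d.shape)
            d = np.where(err, (d + shift) % 3, d).astype(np.int8)
        if config.missing_rate > 0:
            d[rng.random(d.shape) < config.missing_rate] = -1
        blocks.append(d)
        keys.extend((chrom, int(p), "A", ("G",)) for p in haps.positions[chrom])
    return GenotypeMatrix(
        dosages=np.concatenate(blocks, axis=1), samples=samples,
        snp_keys=keys, population=population,
    )


def sample_diploids(haps: HaplotypeSet, n_ind: int, config: SimulationConfig,
                    population: str = "POP",
                    reference: Reference | None = None) -> CallSet:
    """Diploid population by random pairing of haplotypes without
    replacement (a haplotype is never paired with itself), with missing
    genotypes at ``missing_rate`` and errors at ``genotype_error_rate``.
    """
    if 2 * n_ind > haps.n_haplotypes:
        raise ValueError(
            f"n_ind={n_ind} needs {2 * n_ind} haplotypes, "
            f"have {haps.n_haplotypes}"
        )
    rng = config.rng("diploids")
    perm = rng.permutation(haps.n_haplotypes)[: 2 * n_ind]
    pairs = perm.reshape(n_ind, 2)
    samples = [f"{population}_{i + 1:03d}" for i in range(n_ind)]
    roster = SampleRoster(entries={
        s: RosterEntry(population=population, role=DIPLOID) for s in samples
    })
    alleles = _allele_table(haps, reference, config)
    records: list[VariantRecord] = []
    for chrom in haps.positions:
        pos = haps.positions[chrom]
        H = haps.haplotypes[chrom]
        A = H[pairs[:, 0]]  # n_ind x M
        B = H[pairs[:, 1]]
        miss = (
            rng.random((n_ind, len(pos))) < config.missing_rate
            if config.missing_rate > 0 else None
        )
        for j, p in enumerate(pos):
            gts: list = []
            for i in range(n_ind):
                if miss is not None and miss[i, j]:
                    gts.append((None, None))
                    continue
                gt = (int(A[i, j]), int(B[i, j]))
                gt = _apply_genotype_errors(
                    tuple(sorted(gt)), rng, config.genotype_error_rate
                )
                gts.append(gt)
            ref_b, alt_b = alleles[chrom][j]
            records.append(
                VariantRecord(chrom=chrom, pos=int(p), ref=ref_b,
                              alts=(alt_b,), genotypes=gts)
            )
    return CallSet(records=records, samples=samples, roster=roster,
                   provenance={population: "synthetic diploids"})
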