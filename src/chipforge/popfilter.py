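"""Population-genetic site filters used to clean multi-population variant
catalogues before array design.

Covers the cleaning cascade applied to whole-genome-sequencing call sets:
bi-allelism and chromosome allow-lists with a minor-allele-frequency floor,
replicate-concordance checks across resequenced isogenic (doubled-haploid)
lines, the paralogous-sequence-variant (PSV) screen based on heterozygosity
in doubled haploids — DH fish carry two identical chromosome sets, so a
heterozygous call almost always marks collapsed duplicated copies rather
than a real allele — and a completeness filter.

Conventions (documented once, applied everywhere):

* MAF boundary: keep iff MAF >= maf_min.
* Half-missing genotypes (``./1``) count as missing.
* A replicate line with one sample missing at a site is NOT discordant:
  missingness is not evidence of inconsistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .variantstore import CallSet, VariantRecord

__all__ = [
    "RosterEntry",
    "SampleRoster",
    "NoCalledAllelesError",
    "compute_maf",
    "clean_database",
    "replicate_concordance_filter",
    "dh_heterozygosity_filter",
    "fully_genotyped_filter",
]

DOUBLED_HAPLOID = "doubled_haploid"
DIPLOID = "diploid"


class NoCalledAllelesError(ValueError):
    """MAF is undefined when every genotype in the subset is missing —
    distinct from a true frequency of 0.0."""


@dataclass(frozen=True)
class RosterEntry:
    population: str
    role: str  # doubled_haploid | diploid
    line_id: str | None = None
    replicate_group: str | None = None
    depth_rank: int = 0  # higher = deeper sequencing, wins replicate tie-break

    def __post_init__(self) -> None:
        if self.role not in (DOUBLED_HAPLOID, DIPLOID):
            raise ValueError(f"unknown role {self.role!r}")
        if self.replicate_group is not None and self.line_id is None:
            raise ValueError("replicate_group implies line_id")


@dataclass
class SampleRoster:
    entries: dict[str, RosterEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lines_seen: dict[str, str] = {}
        for sid, e in self.entries.items():
            if e.role == DOUBLED_HAPLOID and e.line_id is not None:
                # several samples may carry the same line_id only as replicates
                if e.line_id in lines_seen and e.replicate_group is None:
                    raise ValueError(
                        f"line_id {e.line_id!r} reused outside a replicate group"
                    )
                lines_seen.setdefault(e.line_id, sid)

    def samples_in_population(self, population: str) -> list[str]:
        return [s for s, e in self.entries.items() if e.population == population]

    def dh_samples(self) -> list[str]:
        return [s for s, e in self.entries.items() if e.role == DOUBLED_HAPLOID]

    def replicate_lines(self) -> dict[str, list[str]]:
        """line_id -> sample ids, for lines sequenced more than once."""
        by_line: dict[str, list[str]] = {}
        for s, e in self.entries.items():
            if e.line_id is not None:
                by_line.setdefault(e.line_id, []).append(s)
        return {k: v for k, v in by_line.items() if len(v) > 1}

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tline_id\treplicate_group\trole\tpopulation\tdepth_rank\n")
            for sid, e in self.entries.items():
                fh.write(
                    f"{sid}\t{e.line_id or '.'}\t{e.replicate_group or '.'}\t"
                    f"{e.role}\t{e.population}\t{e.depth_rank}\n"
                )

    @classmethod
    def from_tsv(cls, path: str) -> "SampleRoster":
        entries: dict[str, RosterEntry] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                f = line.rstrip("\n").split("\t")
                entries[f[idx["sample_id"]]] = RosterEntry(
                    population=f[idx["population"]],
                    role=f[idx["role"]],
                    line_id=None if f[idx["line_id"]] == "." else f[idx["line_id"]],
                    replicate_group=(
                        None if f[idx["replicate_group"]] == "."
                        else f[idx["replicate_group"]]
                    ),
                    depth_rank=int(f[idx["depth_rank"]]),
                )
        return cls(entries=entries)


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def compute_maf(record: VariantRecord, sample_indices: Sequence[int]) -> float:
    """Minor allele frequency over called alleles in the subset.

    MAF = min(p, 1-p) with p the alt-allele fraction of called alleles;
    missing (or half-missing) genotypes drop out of the denominator.
    Raises :class:`NoCalledAllelesError` when nothing is called.
    """
    if not record.is_biallelic:
        raise ValueError(
            f"MAF needs a bi-allelic record, got {record.chrom}:{record.pos} "
            f"with alts {record.alts}"
        )
    alt = called = 0
    for i in sample_indices:
        a, b = record.genotypes[i]
        if a is None or b is None:
            continue
        called += 2
        # int() guards against numpy bools, whose "+" is logical
        alt += int(a != 0) + int(b != 0)
    if called == 0:
        raise NoCalledAllelesError(f"{record.chrom}:{record.pos}")
    p = alt / called
    return min(p, 1.0 - p)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def clean_database(callset: CallSet, population: str, maf_min: float = 0.01,
                   chroms: Iterable[str] = (), roster: SampleRoster | None = None,
                   ledger=None) -> CallSet:
    """Database cleaning: keep bi-allelic SNPs on allowed chromosomes with
    MAF >= maf_min in the named population.

    Sites where no allele is called in the population are removed (their
    MAF is undefined, not zero).  The mitochondrial chromosome is handled
    through the allow-list like any other sequence.
    """
    allow = set(chroms)
    if not allow:
        raise ValueError("chroms allow-list must be non-empty")
    roster = roster if roster is not None else callset.roster
    if roster is None:
        raise ValueError("a sample roster is required to resolve the population")
    pop_samples = roster.samples_in_population(population)
    if not pop_samples:
        raise KeyError(f"population {population!r} absent from roster")
    idx = [callset.sample_index(s) for s in pop_samples]
    kept: list[VariantRecord] = []
    for r in callset.records:
        if r.chrom not in allow or not r.is_biallelic:
            continue
        try:
            maf = compute_maf(r, idx)
        except NoCalledAllelesError:
            continue
        if maf >= maf_min:
            kept.append(r)
    if ledger is not None:
        ledger.record("clean_database", len(callset.records), len(kept))
    return callset.subset_records(kept)


def _called_gt(g) -> frozenset | None:
    a, b = g
    if a is None or b is None:
        return None
    return frozenset((a, b))


def replicate_concordance_filter(callset: CallSet,
                                 roster: SampleRoster | None = None,
                                 max_discordant_lines: int = 1,
                                 ledger=None) -> CallSet:
    """Remove sites where more than ``max_discordant_lines`` replicated
    lines show internally inconsistent genotypes, then keep exactly one
    sample per line (deepest sequencing).

    A line is discordant at a site when two of its replicate samples carry
    different *called* genotypes (unordered allele comparison); a missing
    replicate never creates discordance.
    """
    roster = roster if roster is not None else callset.roster
    if roster is None:
        raise ValueError("roster required")
    rep_lines = roster.replicate_lines()
    if not rep_lines:
        raise ValueError("no replicated lines in roster")
    rep_idx = {
        line: [callset.sample_index(s) for s in samples]
        for line, samples in rep_lines.items()
    }
    kept: list[VariantRecord] = []
    for r in callset.records:
        discordant = 0
        for idxs in rep_idx.values():
            calls = {g for g in (_called_gt(r.genotypes[i]) for i in idxs)
                     if g is not None}
            if len(calls) > 1:
                discordant += 1
        if discordant <= max_discordant_lines:
            kept.append(r)

    # deduplicate: one sample per line, deepest sequencing wins
    drop: set[str] = set()
    for line, samples in rep_lines.items():
        ranked = sorted(
            samples, key=lambda s: (roster.entries[s].depth_rank, s)
        )
        drop.update(ranked[:-1])
    keep_samples = [s for s in callset.samples if s not in drop]
    keep_idx = [callset.sample_index(s) for s in keep_samples]
    new_records = [
        VariantRecord(
            chrom=r.chrom, pos=r.pos, ref=r.ref, alts=r.alts, qual=r.qual,
            info=dict(r.info), genotypes=[r.genotypes[i] for i in keep_idx],
            vid=r.vid, filter=r.filter,
        )
        for r in kept
    ]
    new_roster = SampleRoster(
        entries={s: roster.entries[s] for s in keep_samples
                 if s in roster.entries}
    )
    if ledger is not None:
        ledger.record("replicate_concordance", len(callset.records),
                      len(new_records))
    return CallSet(records=new_records, samples=keep_samples,
                   roster=new_roster, provenance=dict(callset.provenance))


def dh_heterozygosity_filter(callset: CallSet,
                             roster: SampleRoster | None = None,
                             max_het: int = 1, ledger=None) -> CallSet:
    """PSV screen: remove sites where more than ``max_het`` doubled-haploid
    samples are heterozygous.

    DH individuals are fully homozygous, so heterozygous calls flag
    paralogous sequence variants (reads from duplicated copies collapsing
    onto one locus).  ``max_het=1`` reproduces the strict screen (filter at
    >= 2 het DH samples); ``max_het=4`` the relaxed preselection rule.
    """
    roster = roster if roster is not None else callset.roster
    if roster is None:
        raise ValueError("roster required")
    dh = roster.dh_samples()
    dh = [s for s in dh if s in callset.samples]
    if not dh:
        raise ValueError("no doubled-haploid samples: filter is meaningless")
    idx = [callset.sample_index(s) for s in dh]
    kept = [
        r for r in callset.records
        if sum(r.is_het(i) for i in idx) <= max_het
    ]
    if ledger is not None:
        ledger.record(f"dh_heterozygosity[max_het={max_het}]",
                      len(callset.records), len(kept))
    return callset.subset_records(kept)


def fully_genotyped_filter(callset: CallSet,
                           sample_subset: Sequence[str] | None = None,
                           ledger=None) -> CallSet:
    """Keep only sites fully genotyped (no missing call) across the subset."""
    samples = list(sample_subset) if sample_subset else list(callset.samples)
    if not samples:
        raise ValueError("sample subset must be non-empty")
    idx = [callset.sample_index(s) for s in samples]
    kept = [
        r for r in callset.records
        if not any(r.is_missing(i) for i in idx)
    ]
    if ledger is not None:
        ledger.record("fully_genotyped", len(callset.records), len(kept))
    return callset.subset_records(kept)
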