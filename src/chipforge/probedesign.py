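"""Array-candidate selection: spacing, flank extraction and trimming,
probe uniqueness, ambiguity screening, density balancing, legacy-marker
retention and panel assembly.

Array probes hybridise to the up-to-50 bp of reference sequence flanking a
SNP, so candidates must be well separated from neighbouring polymorphism
(monomorphic probe sequence), locally unique in the genome (no paralogous
cross-hybridisation), free of long ambiguous-base runs, and not of the
strand-flip-ambiguous allele types {A,T}/{C,G} that need four probes
instead of two.  Density balancing thins SNP-rich regions by minor-allele
frequency so the panel tiles the genome evenly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._scan import Hit, exact_hits, revcomp, scored_hits
from .variantstore import CallSet, VariantRecord

__all__ = [
    "ProbeCandidate",
    "UniquenessResult",
    "RoundSpec",
    "spacing_filter",
    "extract_flanks",
    "trim_flank_n_runs",
    "flank_uniqueness",
    "classify_ambiguity",
    "density_adjust",
    "preselect",
    "assemble_panel",
    "panel_to_tsv",
    "panel_to_fasta",
    "candidates_from_callset",
]

AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


@dataclass
class ProbeCandidate:
    """A variant with its probe context and selection annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    left_flank: str = ""
    right_flank: str = ""
    trimmed: tuple[bool, bool] = (False, False)
    trim_keep: bool = True
    ambiguous: bool = False
    maf_by_population: dict[str, float] = field(default_factory=dict)
    designable: str = "unknown"  # recommended | neutral | not_recommended | unknown
    legacy: bool = False
    unique: bool | None = None
    het_dh_lines: int | None = None
    biallelic: bool = True

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def max_maf(self) -> float:
        return max(self.maf_by_population.values(), default=0.0)


# ---------------------------------------------------------------------------
# spacing
# ---------------------------------------------------------------------------

def spacing_filter(callset: CallSet, min_distance: int = 50,
                   ledger=None) -> CallSet:
    """Keep sites at least ``min_distance`` bp from the nearest site of the
    FULL input catalogue (not the surviving set).

    The nearest neighbour is measured against every identified variant, so
    two close sites knock each other out; a boundary distance of exactly
    ``min_distance`` is kept ("at least").
    """
    kept: list[VariantRecord] = []
    by_chrom: dict[str, list[VariantRecord]] = {}
    for r in callset.records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for recs in by_chrom.values():
        pos = np.array([r.pos for r in recs])
        if len(pos) == 1:
            kept.append(recs[0])
            continue
        gap_prev = np.diff(pos, prepend=pos[0] - 10 * min_distance)
        gap_next = np.diff(pos, append=pos[-1] + 10 * min_distance)
        ok = (gap_prev >= min_distance) & (gap_next >= min_distance)
        kept.extend(r for r, k in zip(recs, ok) if k)
    if ledger is not None:
        ledger.record(f"spacing[{min_distance}bp]",
                      len(callset.records), len(kept))
    return callset.subset_records(kept)


# ---------------------------------------------------------------------------
# flanks
# ---------------------------------------------------------------------------

def _chrom_seq(reference: Mapping[str, object], chrom: str) -> str:
    return str(reference[chrom]).upper()


def extract_flanks(reference: Mapping[str, object], variant,
                   flank_len: int = 50) -> tuple[str, str]:
    """Reference sequence each side of the variant base (excluded),
    truncated at chromosome ends.

    ``variant`` needs ``chrom`` and 1-based ``pos`` attributes.
    """
    seq = _chrom_seq(reference, variant.chrom)
    p = variant.pos
    if not 1 <= p <= len(seq):
        raise IndexError(
            f"position {variant.chrom}:{p} beyond chromosome end ({len(seq)})"
        )
    left = seq[max(0, p - 1 - flank_len): p - 1]
    right = seq[p: p + flank_len]
    return left, right


def trim_flank_n_runs(left: str, right: str, max_run: int = 3,
                      min_short: int = 20, full_len: int = 50,
                      ) -> tuple[str, str, bool]:
    """Trim each flank at runs of more than ``max_run`` consecutive N,
    keeping the variant-proximal segment (probes anchor at the variant).

    The candidate is kept iff the shorter trimmed flank is at least
    ``min_short`` bp AND the longer one retains the full ``full_len`` bp.
    """
    def runs(s: str) -> list[tuple[int, int]]:
        out, i = [], 0
        while i < len(s):
            if s[i] == "N":
                j = i
                while j < len(s) and s[j] == "N":
                    j += 1
                if j - i > max_run:
                    out.append((i, j))
                i = j
            else:
                i += 1
        return out

    lruns = runs(left)
    new_left = left[lruns[-1][1]:] if lruns else left  # variant is at right end
    rruns = runs(right)
    new_right = right[:rruns[0][0]] if rruns else right  # variant at left end
    lens = sorted((len(new_left), len(new_right)))
    keep = lens[0] >= min_short and lens[1] >= full_len
    return new_left, new_right, keep


# ---------------------------------------------------------------------------
# uniqueness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniquenessResult:
    unique: bool
    side: str | None = None  # which flank produced the unique probe
    reason: str = ""

    def __bool__(self) -> bool:
        return self.unique


def flank_uniqueness(candidate: ProbeCandidate,
                     reference: Mapping[str, object],
                     probe_len: int = 35,
                     mode: str = "exact") -> UniquenessResult:
    """True iff for at least one side the variant-proximal ``probe_len``-mer
    has a unique best placement in the reference (forward or reverse
    complement) located on the candidate's chromosome at the expected locus.

    ``mode='exact'`` counts exact occurrences (deterministic, default);
    ``mode='scored'`` scores every ungapped placement (match +1, mismatch
    -1) and requires no co-optimal hit — a near-duplicate copy with a few
    mismatches passes exact search but is still sub-optimal under scoring.
    """
    sides: list[tuple[str, str, int]] = []
    if len(candidate.left_flank) >= probe_len:
        probe = candidate.left_flank[-probe_len:]
        # probe occupies [pos - probe_len, pos) in 0-based terms
        sides.append(("left", probe, candidate.pos - 1 - probe_len))
    if len(candidate.right_flank) >= probe_len:
        sides.append(("right", candidate.right_flank[:probe_len],
                      candidate.pos))
    if not sides:
        return UniquenessResult(False, None, "both flanks shorter than probe")

    for side, probe, expected_start in sides:
        if mode == "exact":
            hits = exact_hits(probe, reference)
            best = hits
        elif mode == "scored":
            hits = scored_hits(probe, reference, min_identity=0.5)
            if not hits:
                continue
            top = max(h.score for h in hits)
            best = [h for h in hits if h.score == top]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if len(best) == 1 and best[0].chrom == candidate.chrom \
                and best[0].strand == "+" and best[0].start == expected_start:
            return UniquenessResult(True, side, "unique best hit at locus")
    return UniquenessResult(False, None, "no side with a unique best hit")


# ---------------------------------------------------------------------------
# ambiguity
# ---------------------------------------------------------------------------

def classify_ambiguity(ref: str, alt: str) -> bool:
    """A/T and C/G allele pairs are strand-flip invariant (need 4 probes)."""
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT single-base alleles required: {ref}/{alt}")
    return frozenset((ref, alt)) in AMBIGUOUS_PAIRS


# ---------------------------------------------------------------------------
# density balancing
# ---------------------------------------------------------------------------

def density_adjust(candidates: Sequence[ProbeCandidate],
                   window: int = 100_000, max_per_window: int = 30,
                   maf_floor: float = 0.15,
                   ledger=None) -> list[ProbeCandidate]:
    """In 0-anchored tiled windows holding MORE than ``max_per_window``
    candidates, keep only those whose best per-population MAF reaches
    ``maf_floor``; other windows pass through untouched.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    counts: dict[tuple[str, int], int] = {}
    for c in candidates:
        w = (c.chrom, (c.pos - 1) // window)
        counts[w] = counts.get(w, 0) + 1
    kept = [
        c for c in candidates
        if counts[(c.chrom, (c.pos - 1) // window)] <= max_per_window
        or c.max_maf >= maf_floor
    ]
    if ledger is not None:
        ledger.record("density_adjust", len(candidates), len(kept))
    return kept


# ---------------------------------------------------------------------------
# preselection rounds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoundSpec:
    """One preselection round.

    ``maf_floors`` maps population name -> floor; ``quantifier`` 'all'
    requires every named population to reach its floor, 'any' at least one.
    """

    maf_floors: Mapping[str, float]
    quantifier: str = "all"
    require_biallelic: bool = True
    max_het_lines: int | None = 4
    require_unique: bool = True
    require_trim_keep: bool = True

    def __post_init__(self) -> None:
        if self.quantifier not in ("all", "any"):
            raise ValueError("quantifier must be 'all' or 'any'")


def preselect(candidates: Sequence[ProbeCandidate], round_spec: RoundSpec,
              ledger=None) -> list[ProbeCandidate]:
    """Conjunction of the configured predicates, applied in declared order
    with per-predicate attrition recorded."""

    def maf_ok(c: ProbeCandidate) -> bool:
        checks = []
        for pop, floor in round_spec.maf_floors.items():
            if pop not in c.maf_by_population:
                checks.append(False)
            else:
                checks.append(c.maf_by_population[pop] >= floor)
        if not checks:
            return True
        return all(checks) if round_spec.quantifier == "all" else any(checks)

    for pop in round_spec.maf_floors:
        known = {p for c in candidates for p in c.maf_by_population}
        if candidates and pop not in known:
            raise KeyError(f"population {pop!r} unknown to every candidate")

    predicates: list[tuple[str, callable]] = [("maf", maf_ok)]
    if round_spec.require_biallelic:
        predicates.append(("biallelic", lambda c: c.biallelic))
    if round_spec.max_het_lines is not None:
        predicates.append((
            f"dh_het<= {round_spec.max_het_lines}",
            lambda c: (c.het_dh_lines or 0) <= round_spec.max_het_lines,
        ))
    if round_spec.require_unique:
        predicates.append(("unicity", lambda c: bool(c.unique)))
    if round_spec.require_trim_keep:
        predicates.append(("trimming", lambda c: c.trim_keep))

    surviving = list(candidates)
    for name, pred in predicates:
        n_in = len(surviving)
        surviving = [c for c in surviving if pred(c)]
        if ledger is not None:
            ledger.record(f"preselect[{name}]", n_in, len(surviving))
    return surviving


# ---------------------------------------------------------------------------
# panel assembly
# ---------------------------------------------------------------------------

def assemble_panel(selected: Sequence[ProbeCandidate],
                   legacy_markers: Sequence[ProbeCandidate] = (),
                   designability: Mapping[tuple, str] | None = None,
                   ) -> list[ProbeCandidate]:
    """Final panel: (selected ∪ legacy) minus candidates annotated
    ``not_recommended``; ambiguous candidates are excluded from the new
    selection but legacy markers are exempt; duplicate keys collapse with
    the legacy flag preserved.
    """
    designability = dict(designability or {})
    by_key: dict[tuple, ProbeCandidate] = {}
    for c in selected:
        ann = designability.get(c.key, c.designable or "unknown")
        if ann == "not_recommended" or c.ambiguous:
            continue
        by_key[c.key] = replace(c, designable=ann)
    for c in legacy_markers:
        ann = designability.get(c.key, c.designable or "unknown")
        if ann == "not_recommended":
            by_key.pop(c.key, None)
            continue
        if c.key in by_key:
            existing = by_key[c.key]
            if (existing.ref, existing.alt) != (c.ref, c.alt):
                raise ValueError(f"conflicting alleles for key {c.key}")
            by_key[c.key] = replace(existing, legacy=True)
        else:
            by_key[c.key] = replace(c, legacy=True, designable=ann)
    return sorted(by_key.values(), key=lambda c: (c.chrom, c.pos, c.alt))


def panel_to_tsv(panel: Sequence[ProbeCandidate], path: str) -> None:
    with open(path, "w") as fh:
        pops = sorted({p for c in panel for p in c.maf_by_population})
        cols = ["chrom", "pos", "ref", "alt", "left_flank", "right_flank",
                "designable", "legacy"] + [f"maf_{p}" for p in pops]
        fh.write("\t".join(cols) + "\n")
        for c in panel:
            row = [c.chrom, str(c.pos), c.ref, c.alt, c.left_flank,
                   c.right_flank, c.designable, str(int(c.legacy))]
            row += [
                f"{c.maf_by_population[p]:.4f}" if p in c.maf_by_population
                else "." for p in pops
            ]
            fh.write("\t".join(row) + "\n")


def panel_to_fasta(panel: Sequence[ProbeCandidate], path: str) -> None:
    """Probe sequences with the variant encoded as [ref/alt] in-line
    (submission style for array manufacture)."""
    with open(path, "w") as fh:
        for c in panel:
            fh.write(f">{c.chrom}_{c.pos}_{c.ref}_{c.alt}\n")
            fh.write(f"{c.left_flank}[{c.ref}/{c.alt}]{c.right_flank}\n")


def candidates_from_callset(callset: CallSet,
                            reference: Mapping[str, object],
                            maf_by_population: Mapping[str, Mapping[tuple, float]]
                            | None = None,
                            flank_len: int = 50) -> list[ProbeCandidate]:
    """Convenience constructor: build probe candidates with flanks, trim
    state and ambiguity from a cleaned call set."""
    out: list[ProbeCandidate] = []
    for r in callset.records:
        if not r.is_biallelic:
            continue
        left, right = extract_flanks(reference, r, flank_len)
        tl, tr, keep = trim_flank_n_runs(left, right, full_len=flank_len)
        alt = r.alts[0]
        try:
            amb = classify_ambiguity(r.ref, alt)
        except ValueError:
            continue  # non-SNP alleles are not probe candidates
        mafs = {
            pop: table[(r.chrom, r.pos)]
            for pop, table in (maf_by_population or {}).items()
            if (r.chrom, r.pos) in table
        }
        out.append(ProbeCandidate(
            chrom=r.chrom, pos=r.pos, ref=r.ref, alt=alt,
            left_flank=tl, right_flank=tr,
            trimmed=(tl != left, tr != right), trim_keep=keep,
            ambiguous=amb, maf_by_population=mafs,
        ))
    return out
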