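"""VCF-backed variant data model: reading, writing, merging, intersection and
INFO-field hard filtering.

The in-memory model is deliberately small: a :class:`CallSet` is an ordered
list of :class:`VariantRecord` plus a sample roster.  VCF v4.2 is the sole
interchange format between the synthetic-data generator and the design
pipeline, so synthetic and real data follow one code path.  Reading goes
through :mod:`cyvcf2`; writing emits plain VCF text (GT only plus whatever
INFO keys the records carry).

Coordinates are 1-based inclusive externally (VCF convention); any internal
interval arithmetic in this package is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Sequence

import numpy as np
from cyvcf2 import VCF

__all__ = [
    "Genotype",
    "VariantRecord",
    "CallSet",
    "UnsortedVCFError",
    "read_vcf",
    "write_vcf",
    "merge_callsets",
    "intersect_callsets",
    "filter_info_thresholds",
    "parse_filter_expression",
]

#: per-sample genotype: pair of allele indices, ``None`` meaning missing.
Genotype = tuple[int | None, int | None]

MISSING: Genotype = (None, None)

# INFO keys the pipeline's hard filters may reference, with VCF types for
# header reconstruction on write.
_INFO_TYPES = {
    "DP": ("1", "Integer"),
    "MQ": ("1", "Float"),
    "QD": ("1", "Float"),
    "FS": ("1", "Float"),
    "SOR": ("1", "Float"),
    "MQRankSum": ("1", "Float"),
    "ReadPosRankSum": ("1", "Float"),
    "AN": ("1", "Integer"),
}


class UnsortedVCFError(ValueError):
    """Input VCF is not coordinate-sorted; carries the first offending site."""


@dataclass
class VariantRecord:
    """One VCF site.

    ``genotypes`` holds one ``(a, b)`` pair of allele indices per sample in
    roster order; half-missing calls are normalised to fully missing at
    construction time by callers that care (the population filters treat
    them as missing regardless).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    info: dict[str, Any] = field(default_factory=dict)
    genotypes: list[Genotype] = field(default_factory=list)
    vid: str = "."
    filter: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or any(not a for a in self.alts):
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref in self.alts:
            raise ValueError(f"ref allele {self.ref!r} repeated in alts")
        n_alleles = 1 + len(self.alts)
        for g in self.genotypes:
            for a in g:
                if a is not None and not (0 <= a < n_alleles):
                    raise ValueError(
                        f"genotype allele index {a} out of range at "
                        f"{self.chrom}:{self.pos}"
                    )

    @property
    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        return (self.chrom, self.pos, self.ref, self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def is_het(self, sample_index: int) -> bool:
        a, b = self.genotypes[sample_index]
        return a is not None and b is not None and a != b

    def is_missing(self, sample_index: int) -> bool:
        a, b = self.genotypes[sample_index]
        return a is None or b is None


@dataclass
class CallSet:
    """Ordered variant records plus a sample roster.

    ``roster`` is an optional :class:`chipforge.popfilter.SampleRoster`
    carrying role metadata (doubled-haploid line ids, replicate groups,
    population labels); kept untyped here to avoid a circular import.
    """

    records: list[VariantRecord]
    samples: list[str]
    roster: Any = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in roster")
        seen: set[tuple] = set()
        for r in self.records:
            if len(r.genotypes) != len(self.samples):
                raise ValueError(
                    f"record {r.chrom}:{r.pos} has {len(r.genotypes)} "
                    f"genotypes for {len(self.samples)} samples"
                )
            if r.key in seen:
                raise ValueError(f"duplicate record key {r.key}")
            seen.add(r.key)
        _check_sorted(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def subset_records(self, keep: Iterable[VariantRecord]) -> "CallSet":
        keep_keys = {r.key for r in keep}
        return CallSet(
            records=[r for r in self.records if r.key in keep_keys],
            samples=list(self.samples),
            roster=self.roster,
            provenance=dict(self.provenance),
        )


def _check_sorted(records: Sequence[VariantRecord]) -> None:
    """Chromosome blocks must be contiguous and positions non-decreasing."""
    seen_chroms: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = 0
    for r in records:
        if r.chrom != prev_chrom:
            if r.chrom in seen_chroms:
                raise UnsortedVCFError(
                    f"chromosome {r.chrom} re-appears at {r.chrom}:{r.pos}"
                )
            seen_chroms.add(r.chrom)
            prev_chrom, prev_pos = r.chrom, 0
        if r.pos < prev_pos:
            raise UnsortedVCFError(
                f"position {r.chrom}:{r.pos} after {r.chrom}:{prev_pos}"
            )
        prev_pos = r.pos


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> CallSet:
    """Read a VCF v4.2 file into a :class:`CallSet`.

    Rejects coordinate-unsorted input with the position of the first
    violation.  Half-missing genotypes are kept as given (``(None, 1)``
    etc.); downstream filters treat them as missing.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        alts = tuple(v.ALT)
        gts: list[Genotype] = []
        for g in v.genotypes:
            a = None if g[0] < 0 else int(g[0])
            b = None if g[1] < 0 else int(g[1]) if len(g) > 2 else None
            gts.append((a, b))
        info = {k: _coerce_info(val) for k, val in dict(v.INFO).items()}
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=alts,
                qual=v.QUAL,
                info=info,
                genotypes=gts,
                vid=v.ID or ".",
                filter=v.FILTER,
            )
        )
    vcf.close()
    return CallSet(records=records, samples=samples)


def _coerce_info(val: Any) -> Any:
    if isinstance(val, bytes):
        return val.decode()
    if isinstance(val, (np.floating,)):
        return float(val)
    if isinstance(val, (np.integer,)):
        return int(val)
    return val


def _fmt_info_value(v: Any) -> str:
    if isinstance(v, bool):
        return ""
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _fmt_gt(g: Genotype) -> str:
    a = "." if g[0] is None else str(g[0])
    b = "." if g[1] is None else str(g[1])
    return f"{a}/{b}"


def write_vcf(callset: CallSet, path: str,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a :class:`CallSet` as VCF v4.2 text (GT format field only)."""
    info_keys: list[str] = []
    for r in callset.records:
        for k in r.info:
            if k not in info_keys:
                info_keys.append(k)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=chipforge\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(r.chrom for r in callset.records):
                fh.write(f"##contig=<ID={c}>\n")
        for k in info_keys:
            num, typ = _INFO_TYPES.get(k, ("1", "String"))
            fh.write(
                f'##INFO=<ID={k},Number={num},Type={typ},Description="{k}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                "FORMAT"] + list(callset.samples)
        fh.write("\t".join(cols) + "\n")
        for r in callset.records:
            info = (
                ";".join(
                    k if isinstance(v, bool) and v
                    else f"{k}={_fmt_info_value(v)}"
                    for k, v in r.info.items()
                )
                or "."
            )
            qual = "." if r.qual is None else f"{r.qual:.6g}"
            filt = r.filter if r.filter else "PASS"
            row = [
                r.chrom, str(r.pos), r.vid, r.ref, ",".join(r.alts),
                qual, filt, info, "GT",
            ] + [_fmt_gt(g) for g in r.genotypes]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# merge / intersect
# ---------------------------------------------------------------------------

def merge_callsets(a: CallSet, b: CallSet) -> CallSet:
    """Union of sites and samples, reconciling alternate alleles.

    At a shared (chrom, pos, ref) the alt lists are concatenated (a's order
    then b's novel alleles) and b's genotype indices remapped by allele
    string, never positionally — such sites become multi-allelic.  Samples
    absent at a site get missing genotypes.  Conflicting ref alleles at the
    same position keep both records tagged ``FILTER=REF_CONFLICT``
    (excluded from downstream preselection).
    """
    samples = list(a.samples) + [s for s in b.samples if s not in a.samples]
    n_a, n_b = len(a.samples), len(b.samples)
    # map merged sample slot -> (which input, index) ; None = missing
    slot_a = {s: i for i, s in enumerate(a.samples)}
    slot_b = {s: i for i, s in enumerate(b.samples)}

    by_pos: dict[tuple[str, int], list[VariantRecord]] = {}
    order: list[tuple[str, int]] = []
    for r in a.records:
        k = (r.chrom, r.pos)
        if k not in by_pos:
            by_pos[k] = []
            order.append(k)
        by_pos[k].append(_expand_record(r, samples, slot_a))
    for r in b.records:
        k = (r.chrom, r.pos)
        if k not in by_pos:
            by_pos[k] = [_expand_record(r, samples, slot_b)]
            order.append(k)
        else:
            merged = False
            for i, existing in enumerate(by_pos[k]):
                if existing.ref == r.ref:
                    by_pos[k][i] = _merge_site(existing, r, samples, slot_b)
                    merged = True
                    break
            if not merged:
                # ref conflict: keep both, tag both
                by_pos[k] = [replace(x, filter="REF_CONFLICT") for x in by_pos[k]]
                by_pos[k].append(
                    replace(_expand_record(r, samples, slot_b),
                            filter="REF_CONFLICT")
                )

    chrom_order = list(dict.fromkeys(c for c, _ in order))
    records: list[VariantRecord] = []
    for c in chrom_order:
        for _, p in sorted((k for k in order if k[0] == c), key=lambda k: k[1]):
            records.extend(by_pos[(c, p)])
            by_pos[(c, p)] = []  # guard against duplicate visits
    return CallSet(records=records, samples=samples,
                   provenance={**a.provenance, **b.provenance})


def _expand_record(r: VariantRecord, samples: list[str],
                   slot: dict[str, int]) -> VariantRecord:
    gts = [r.genotypes[slot[s]] if s in slot else MISSING for s in samples]
    return replace(r, genotypes=gts, info=dict(r.info))


def _merge_site(existing: VariantRecord, incoming: VariantRecord,
                samples: list[str], slot_b: dict[str, int]) -> VariantRecord:
    alts = list(existing.alts)
    for alt in incoming.alts:
        if alt not in alts:
            alts.append(alt)
    allele_strings = [existing.ref] + alts
    # remap incoming allele indices by allele string
    inc_alleles = [incoming.ref] + list(incoming.alts)
    remap = {i: allele_strings.index(s) for i, s in enumerate(inc_alleles)}
    gts = list(existing.genotypes)
    for s, j in slot_b.items():
        g = incoming.genotypes[j]
        gts[samples.index(s)] = tuple(
            None if x is None else remap[x] for x in g
        )  # type: ignore[assignment]
    return replace(existing, alts=tuple(alts), genotypes=gts)


def intersect_callsets(callsets: Sequence[CallSet],
                       primary_index: int = 0) -> CallSet:
    """Sites present in every input (same chrom, pos, ref and alt set);
    genotypes taken from ``callsets[primary_index]``.

    Models the multi-caller consensus rule: keep only variants called by
    all callers, with the primary caller's genotypes retained.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two call sets to intersect")
    if not (0 <= primary_index < len(callsets)):
        raise IndexError(f"primary_index {primary_index} out of range")

    def keyset(cs: CallSet) -> set[tuple]:
        return {(r.chrom, r.pos, r.ref, frozenset(r.alts)) for r in cs.records}

    shared = keyset(callsets[0])
    for cs in callsets[1:]:
        shared &= keyset(cs)
    primary = callsets[primary_index]
    records = [
        r for r in primary.records
        if (r.chrom, r.pos, r.ref, frozenset(r.alts)) in shared
    ]
    return CallSet(records=records, samples=list(primary.samples),
                   roster=primary.roster, provenance=dict(primary.provenance))


# ---------------------------------------------------------------------------
# INFO hard filtering
# ---------------------------------------------------------------------------

_ATOM_RE = re.compile(
    r"^\s*(?P<key>[A-Za-z_][A-Za-z0-9_]*)\s*"
    r"(?P<op><=|>=|==|!=|<|>)\s*"
    r"(?P<value>-?\d+(?:\.\d+)?(?:[eE]-?\d+)?)\s*$"
)

_OPS = {
    "<": lambda x, y: x < y,
    ">": lambda x, y: x > y,
    "<=": lambda x, y: x <= y,
    ">=": lambda x, y: x >= y,
    "==": lambda x, y: x == y,
    "!=": lambda x, y: x != y,
}


def parse_filter_expression(expr: str) -> list[tuple[str, str, float]]:
    """Parse a GATK-style disjunction ``"QD < 2.0 || MQ < 40.0"`` into
    ``[(key, op, value), ...]``.  ``;``-separated atoms (the VariantFiltration
    shorthand ``"DP < 120; MQ < 30.0"``) are accepted as the same disjunction.
    """
    atoms: list[tuple[str, str, float]] = []
    for part in re.split(r"\|\||;", expr):
        if not part.strip():
            continue
        m = _ATOM_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse filter atom {part.strip()!r}")
        atoms.append((m["key"], m["op"], float(m["value"])))
    return atoms


def filter_info_thresholds(callset: CallSet, rule_expression: str,
                           ledger=None) -> CallSet:
    """Remove records matching ANY atomic predicate of a disjunctive
    INFO/QUAL hard-filter expression.

    A record lacking a referenced key is retained for that predicate (GATK
    convention for missing annotations).  ``QUAL`` refers to the record's
    QUAL column.
    """
    atoms = parse_filter_expression(rule_expression)
    kept: list[VariantRecord] = []
    for r in callset.records:
        hit = False
        for key, op, val in atoms:
            x = r.qual if key == "QUAL" else r.info.get(key)
            if x is None:
                continue
            if _OPS[op](float(x), val):
                hit = True
                break
        if not hit:
            kept.append(r)
    if ledger is not None:
        ledger.record(f"info_filter[{rule_expression}]",
                      len(callset.records), len(kept))
    return CallSet(records=kept, samples=list(callset.samples),
                   roster=callset.roster, provenance=dict(callset.provenance))
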