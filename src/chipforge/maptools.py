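"""Probe remapping to a second genome assembly and marker density / gap
statistics.

Panels designed against one reference often need re-anchoring on a newer
assembly; a probe is trusted there only when its best alignment is
unambiguous.  The internal aligner is an exhaustive ungapped scored scan
(reproducible at desk scale); tabular hits from an external aligner
(blast outfmt-6 style) can be ingested through the same uniqueness logic
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._scan import scored_hits

__all__ = [
    "Placement",
    "map_probes",
    "placements_from_blast_tab",
    "intermarker_stats",
    "density_per_window",
]


@dataclass(frozen=True)
class Placement:
    probe: str
    chrom: str | None  # None when unplaced
    pos: int | None  # 1-based start on the target
    strand: str | None
    score: float
    unique: bool
    status: str  # 'unique' | 'ambiguous' | 'unplaced'


def _resolve(probe: str, hits: list[tuple[str, int, str, float]],
             score_edge: float) -> Placement:
    """Best-hit-edge semantics: the placement is unique iff the best score
    exceeds every other hit's score by more than ``score_edge`` fraction
    (second_best < best * (1 - score_edge))."""
    if not hits:
        return Placement(probe, None, None, None, 0.0, False, "unplaced")
    hits = sorted(hits, key=lambda h: -h[3])
    chrom, start, strand, best = hits[0]
    if len(hits) > 1 and hits[1][3] >= best * (1.0 - score_edge):
        return Placement(probe, None, None, None, best, False, "ambiguous")
    return Placement(probe, chrom, start + 1, strand, best, True, "unique")


def map_probes(probes: Mapping[str, str],
               target_reference: Mapping[str, object],
               identity_min: float = 0.95,
               score_edge: float = 0.1) -> list[Placement]:
    """Place each probe on the target assembly.

    Every full-length ungapped placement (both strands) is scored
    (match +1, mismatch -1); hits below ``identity_min`` are discarded.
    Probes with no surviving hit are 'unplaced'; probes whose best hit is
    not separated from the runner-up by more than ``score_edge`` fraction
    of its score are 'ambiguous'; the rest are uniquely placed.
    """
    if not target_reference or all(
        len(str(s)) == 0 for s in target_reference.values()
    ):
        raise ValueError("empty target reference")
    placements = []
    for name, seq in probes.items():
        if len(seq) < 20:
            raise ValueError(f"probe {name!r} shorter than 20 bp")
        hits = [
            (h.chrom, h.start, h.strand, float(h.score))
            for h in scored_hits(seq, target_reference,
                                 min_identity=identity_min)
        ]
        placements.append(_resolve(name, hits, score_edge))
    return placements


_BLAST6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def placements_from_blast_tab(path: str, identity_min: float = 95.0,
                              score_edge: float = 0.1,
                              all_probes: Sequence[str] | None = None,
                              ) -> list[Placement]:
    """Ingest external aligner hits (tab-separated outfmt-6 columns) and
    apply the same best-hit-edge uniqueness rule on bitscore.

    ``identity_min`` is on the percent scale of the pident column.
    Probes listed in ``all_probes`` but absent from the table are reported
    as unplaced.
    """
    df = pd.read_csv(path, sep="\t", names=_BLAST6_COLS, comment="#")
    df = df[df.pident >= identity_min]
    placements: list[Placement] = []
    seen = set()
    for probe, grp in df.groupby("qseqid", sort=False):
        seen.add(probe)
        hits = [
            (row.sseqid,
             int(min(row.sstart, row.send)) - 1,
             "+" if row.send >= row.sstart else "-",
             float(row.bitscore))
            for row in grp.itertuples()
        ]
        placements.append(_resolve(str(probe), hits, score_edge))
    for probe in all_probes or ():
        if probe not in seen:
            placements.append(
                Placement(probe, None, None, None, 0.0, False, "unplaced")
            )
    return placements


def placements_to_tsv(placements: Sequence[Placement], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("probe\tchrom\tpos\tstrand\tscore\tstatus\n")
        for p in placements:
            fh.write(
                f"{p.probe}\t{p.chrom or '.'}\t{p.pos or '.'}\t"
                f"{p.strand or '.'}\t{p.score:g}\t{p.status}\n"
            )


# ---------------------------------------------------------------------------
# density / gap statistics
# ---------------------------------------------------------------------------

def intermarker_stats(positions_by_chrom: Mapping[str, Sequence[int]],
                      chrom_sizes: Mapping[str, int] | None = None,
                      gap_threshold: int = 10_000,
                      top_k: int = 3) -> dict:
    """Successive-marker gap summary.

    Gaps are position differences within each chromosome; when
    ``chrom_sizes`` is supplied the trailing gap from the last marker to
    the chromosome end is counted too (a panel's largest hole is often
    there).  Returns median/mean gap, the fraction above
    ``gap_threshold`` and the ``top_k`` largest gaps with coordinates.
    """
    gaps: list[float] = []
    located: list[tuple[float, str, int, int]] = []
    for chrom, pos in positions_by_chrom.items():
        p = np.asarray(pos)
        if np.any(np.diff(p) < 0):
            raise ValueError(f"positions on {chrom} are not sorted")
        d = np.diff(p)
        gaps.extend(d.tolist())
        located.extend(
            (float(g), chrom, int(a), int(b))
            for g, a, b in zip(d, p[:-1], p[1:])
        )
        if chrom_sizes and chrom in chrom_sizes and len(p):
            end_gap = chrom_sizes[chrom] - int(p[-1])
            if end_gap > 0:
                gaps.append(end_gap)
                located.append(
                    (float(end_gap), chrom, int(p[-1]), chrom_sizes[chrom])
                )
    g = np.asarray(gaps, dtype=float)
    located.sort(key=lambda t: -t[0])
    return {
        "n_gaps": len(g),
        "median": float(np.median(g)) if len(g) else float("nan"),
        "mean": float(np.mean(g)) if len(g) else float("nan"),
        "fraction_above_threshold": (
            float((g > gap_threshold).mean()) if len(g) else float("nan")
        ),
        "largest": [
            {"gap": gap, "chrom": chrom, "start": a, "end": b}
            for gap, chrom, a, b in located[:top_k]
        ],
    }


def density_per_window(positions_by_chrom: Mapping[str, Sequence[int]],
                       window: int = 1_000_000,
                       chrom_sizes: Mapping[str, int] | None = None,
                       ) -> tuple[pd.DataFrame, dict]:
    """Marker counts in 0-anchored tiled windows plus summary statistics.

    The total count over windows equals the number of input positions.
    With ``chrom_sizes``, empty trailing windows are included so sparse
    chromosome ends show up as zeros.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for chrom, pos in positions_by_chrom.items():
        p = np.asarray(pos)
        size = (chrom_sizes or {}).get(chrom, int(p.max()) if len(p) else 0)
        n_win = max(1, -(-size // window))
        counts = np.bincount((p - 1) // window, minlength=n_win) if len(p) \
            else np.zeros(n_win, dtype=int)
        for w, c in enumerate(counts):
            rows.append((chrom, w * window, int(c)))
    track = pd.DataFrame(rows, columns=["chrom", "start", "count"])
    summary = {
        "total": int(track["count"].sum()),
        "mean": float(track["count"].mean()) if len(track) else float("nan"),
        "median": float(track["count"].median()) if len(track) else float("nan"),
        "min": int(track["count"].min()) if len(track) else 0,
        "max": int(track["count"].max()) if len(track) else 0,
    }
    return track, summary
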