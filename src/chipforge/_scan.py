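"""Exhaustive ungapped sequence search shared by probe uniqueness checks
and probe remapping.

Desk-scale by design: every offset of every chromosome, forward and
reverse-complement, is scored (match +1, mismatch -1, no gaps), so results
are reproducible and independent of any external aligner version.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

__all__ = ["Hit", "revcomp", "exact_hits", "scored_hits"]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Hit:
    chrom: str
    start: int  # 0-based start of the query on the target
    strand: str  # '+' or '-'
    score: int
    identity: float


def _as_str(seq) -> str:
    # tolerate pyfaidx records and plain strings
    return str(seq).upper()


def exact_hits(query: str, reference: Mapping[str, object]) -> list[Hit]:
    """All exact occurrences of ``query`` or its reverse complement."""
    q = query.upper()
    rq = revcomp(q)
    hits: list[Hit] = []
    for chrom, seq in reference.items():
        s = _as_str(seq)
        for strand, pat in (("+", q), ("-", rq)):
            start = s.find(pat)
            while start != -1:
                hits.append(Hit(chrom, start, strand, len(q), 1.0))
                start = s.find(pat, start + 1)
    return hits


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def scored_hits(query: str, reference: Mapping[str, object],
                min_identity: float = 0.0) -> list[Hit]:
    """Every full-length ungapped placement with identity >= min_identity.

    Score = matches - mismatches over the query length.
    """
    q = query.upper()
    k = len(q)
    hits: list[Hit] = []
    for chrom, seq in reference.items():
        s = _as_str(seq)
        if len(s) < k:
            continue
        enc = _encode(s)
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        for strand, pat in (("+", q), ("-", revcomp(q))):
            matches = (windows == _encode(pat)).sum(axis=1)
            identity = matches / k
            ok = np.nonzero(identity >= min_identity)[0]
            for start in ok:
                m = int(matches[start])
                hits.append(
                    Hit(chrom, int(start), strand, 2 * m - k, m / k)
                )
    return hits
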