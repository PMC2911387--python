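"""Exhaustive ungapped overlap alignment of a mate pair.

Mate 2 is reverse-complemented so both reads are expressed on the insert's
forward strand. A candidate placement is parameterised by the signed offset
``t`` of the reverse-complemented mate 2 relative to mate 1: the implied
insert length is ``t + len(rev)``. Offsets ``t >= 0`` with the insert at
least as long as each read give the normal geometry (composite = mate-1
prefix + consensus + mate-2 suffix); negative offsets (insert shorter than a
read) are adapter read-through, where each read runs past the fragment's far
end into adapter sequence and the composite is the insert region alone.

Every placement with overlap length in [min_overlap, min(len1, len2)] over
both geometries is scored as

    score = match_weight * n_match - mismatch_penalty * n_mismatch

where positions with N in either read count as neither match nor mismatch.
Qualities play no role in alignment scoring; they enter at the consensus
stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .fastq import MatePair, reverse_complement

N_ORD = ord("N")


class Geometry(str, Enum):
    NORMAL = "normal"
    READTHROUGH = "readthrough"


@dataclass(frozen=True)
class CandidateAlignment:
    """One ungapped relative placement of a mate pair.

    ``offset`` places the reverse-complemented mate 2 relative to mate 1
    (position of its first base in mate-1 coordinates); ``insert_len`` is the
    implied insert (= composite) length.
    """

    offset: int
    overlap_len: int
    geometry: Geometry
    n_match: int
    n_mismatch: int
    score: float
    insert_len: int

    @property
    def is_normal(self) -> bool:
        return self.geometry is Geometry.NORMAL


@dataclass
class AlignmentScan:
    """All candidate placements of one pair plus the selected best."""

    pair_id: str
    candidates: list[CandidateAlignment]
    best: Optional[CandidateAlignment] = None

    @property
    def mergeable(self) -> bool:
        return bool(self.candidates)


def candidate_offsets(len1: int, len2: int, min_overlap: int) -> range:
    """Offsets of every placement whose string overlap is >= min_overlap."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if min_overlap > min(len1, len2):
        return range(0)
    return range(min_overlap - len2, len1 - min_overlap + 1)


def overlap_span(t: int, len1: int, len2: int) -> tuple[int, int]:
    """Overlapped interval [start, end) in mate-1 coordinates for offset t."""
    return max(0, t), min(len1, t + len2)


def _geometry(insert_len: int, len1: int, len2: int) -> Geometry:
    # Read-through whenever the implied insert is shorter than a read, i.e.
    # synthesis would have proceeded past the fragment end into adapter.
    return (
        Geometry.READTHROUGH
        if insert_len < len1 or insert_len < len2
        else Geometry.NORMAL
    )


def enumerate_candidates(
    pair: MatePair,
    min_overlap: int = 10,
    match_weight: float = 1.0,
    mismatch_penalty: float = 1.0,
) -> AlignmentScan:
    """Score all ungapped placements of a mate pair.

    Returns an :class:`AlignmentScan` whose candidates are ordered by
    (overlap_len, offset); an empty scan (no placement reaches
    ``min_overlap``) flags the pair unmergeable rather than raising.
    """
    if len(pair.fwd) == 0 or len(pair.rev) == 0:
        raise ValueError("both reads must be nonempty")
    rc = reverse_complement(pair.rev)
    f = np.frombuffer(pair.fwd.bases.encode("ascii"), dtype=np.uint8)
    r = np.frombuffer(rc.bases.encode("ascii"), dtype=np.uint8)
    len1, len2 = len(f), len(r)

    candidates = []
    for t in candidate_offsets(len1, len2, min_overlap):
        s, e = overlap_span(t, len1, len2)
        a = f[s:e]
        b = r[s - t : e - t]
        valid = (a != N_ORD) & (b != N_ORD)
        n_match = int(np.count_nonzero((a == b) & valid))
        n_mismatch = int(np.count_nonzero(valid)) - n_match
        insert_len = t + len2
        candidates.append(
            CandidateAlignment(
                offset=t,
                overlap_len=e - s,
                geometry=_geometry(insert_len, len1, len2),
                n_match=n_match,
                n_mismatch=n_mismatch,
                score=match_weight * n_match - mismatch_penalty * n_mismatch,
                insert_len=insert_len,
            )
        )
    candidates.sort(key=lambda c: (c.overlap_len, c.offset))
    scan = AlignmentScan(pair_id=pair.fwd.read_id, candidates=candidates)
    if candidates:
        scan.best = select_best(scan)
    return scan


def select_best(scan: AlignmentScan) -> CandidateAlignment:
    """Pick the maximal-score candidate.

    Ties break toward the larger overlap, then normal geometry over
    read-through, then the larger offset (larger implied insert) — a fully
    deterministic ordering.
    """
    if not scan.candidates:
        raise ValueError(f"pair {scan.pair_id!r}: no candidate alignments")
    return max(
        scan.candidates,
        key=lambda c: (c.score, c.overlap_len, c.is_normal, c.offset),
    )
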