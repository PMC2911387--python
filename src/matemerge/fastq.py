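"""FASTQ input/output with explicit quality-encoding dialects.

Paired-end FASTQ files come in two common Phred encodings: phred33
(Sanger/modern Illumina, quality character = chr(Q + 33)) and phred64
(Illumina pipelines of the GAII era, chr(Q + 64)). The reader supports both
plus an ``auto`` mode that inspects the quality characters of both files
before yielding any record: any ordinal below 64 is impossible under phred64
and forces phred33; any ordinal above 93 (Q60 in phred33, the highest quality
this package emits) forces phred64. Files whose characters stay inside the
ambiguous band decode identically enough to matter only at Q>25; we default
to phred33 and log the decision.

Qualities are clamped to [0, 60] at ingest, lowercase bases are uppercased,
and any base outside {A, C, G, T, N} is a hard error with file/record
context. Gzip-compressed files (``.gz`` suffix) are read and written
transparently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from os import PathLike
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

QUAL_MAX = 60
#: quality assigned when neither mate is informative (both bases N)
QUAL_UNINFORMATIVE = 2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_BASE_OK = np.zeros(256, dtype=bool)
for _c in b"ACGTNacgtn":
    _BASE_OK[_c] = True


class Encoding(str, Enum):
    """FASTQ quality-character dialect."""

    PHRED33 = "phred33"
    PHRED64 = "phred64"
    AUTO = "auto"

    @property
    def offset(self) -> int:
        if self is Encoding.AUTO:
            raise ValueError("auto encoding has no offset; resolve it first")
        return 33 if self is Encoding.PHRED33 else 64


class FastqFormatError(ValueError):
    """Raised on malformed or inconsistent FASTQ input."""


@dataclass
class ReadRecord:
    """One sequenced read: id, bases over {A,C,G,T,N}, per-base Phred quals."""

    read_id: str
    bases: str
    quals: np.ndarray
    mate: int = 1

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} qualities"
            )
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")

    def __len__(self) -> int:
        return len(self.bases)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadRecord):
            return NotImplemented
        return (
            self.read_id == other.read_id
            and self.bases == other.bases
            and self.mate == other.mate
            and np.array_equal(self.quals, other.quals)
        )


@dataclass
class MatePair:
    """A mate pair: mate 1 as sequenced, mate 2 as sequenced (opposite strand)."""

    fwd: ReadRecord
    rev: ReadRecord

    def __post_init__(self) -> None:
        if self.fwd.mate != 1 or self.rev.mate != 2:
            raise ValueError("MatePair requires fwd.mate == 1 and rev.mate == 2")


def reverse_complement(r: ReadRecord) -> ReadRecord:
    """Reverse-complement a read (N maps to N); qualities are reversed too."""
    return ReadRecord(
        read_id=r.read_id,
        bases=r.bases.translate(_COMPLEMENT)[::-1],
        quals=r.quals[::-1].copy(),
        mate=r.mate,
    )


PathLikeT = Union[str, PathLike]


def _open_text(path: PathLikeT, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _scan_quality_ordinals(path: PathLikeT) -> tuple[int, int]:
    """Return (min, max) quality-character ordinal over a FASTQ file."""
    lo, hi = 255, 0
    with _open_text(path) as fh:
        for _, _, qual in FastqGeneralIterator(fh):
            if qual:
                q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
                lo = min(lo, int(q.min()))
                hi = max(hi, int(q.max()))
                if lo < 64:
                    return lo, hi  # already decisive for phred33
    return lo, hi


def detect_encoding(*paths: PathLikeT) -> Encoding:
    """Infer the quality encoding from observed quality-character ordinals.

    Any ordinal < 64 forces phred33; otherwise any ordinal > 93 forces
    phred64; files confined to [64, 93] are ambiguous and default to phred33
    (logged).
    """
    lo, hi = 255, 0
    for p in paths:
        plo, phi = _scan_quality_ordinals(p)
        lo, hi = min(lo, plo), max(hi, phi)
        if lo < 64:
            return Encoding.PHRED33
    if lo == 255:
        log.info("encoding auto-detect: empty input, defaulting to phred33")
        return Encoding.PHRED33
    if hi > 93:
        return Encoding.PHRED64
    log.info(
        "encoding auto-detect: quality ordinals in [%d, %d] are ambiguous; "
        "defaulting to phred33",
        lo,
        hi,
    )
    return Encoding.PHRED33


def _decode_record(
    title: str,
    seq: str,
    qual: str,
    encoding: Encoding,
    mate: int,
    path: PathLikeT,
    record_no: int,
) -> ReadRecord:
    if len(seq) != len(qual):
        raise FastqFormatError(
            f"{path} record {record_no}: sequence/quality length mismatch"
        )
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if not _BASE_OK[raw].all():
        bad = seq[int(np.argmin(_BASE_OK[raw]))]
        raise FastqFormatError(
            f"{path} record {record_no}: invalid base character {bad!r}"
        )
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
    q -= encoding.offset
    if len(q) and int(q.min()) < 0:
        raise FastqFormatError(
            f"{path} record {record_no}: quality character below the "
            f"{encoding.value} range"
        )
    np.minimum(q, QUAL_MAX, out=q)
    return ReadRecord(title.split()[0], seq.upper(), q, mate=mate)


def read_fastq(
    path: PathLikeT, encoding: Encoding = Encoding.PHRED33, mate: int = 1
) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a single FASTQ file."""
    if encoding is Encoding.AUTO:
        encoding = detect_encoding(path)
    with _open_text(path) as fh:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh), 1):
            yield _decode_record(title, seq, qual, encoding, mate, path, i)


def read_fastq_pairs(
    path_1: PathLikeT,
    path_2: PathLikeT,
    encoding: Encoding = Encoding.AUTO,
) -> Iterator[MatePair]:
    """Stream order-matched mate pairs from two FASTQ files.

    Records are paired by file order (no id-based re-pairing); a record count
    mismatch is a hard error naming the first orphan id.
    """
    if isinstance(encoding, str):
        encoding = Encoding(encoding)
    if encoding is Encoding.AUTO:
        encoding = detect_encoding(path_1, path_2)
        log.info("auto-detected quality encoding: %s", encoding.value)
    it1 = read_fastq(path_1, encoding, mate=1)
    it2 = read_fastq(path_2, encoding, mate=2)
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            orphan = r2 if r1 is sentinel else r1
            short = path_1 if r1 is sentinel else path_2
            raise FastqFormatError(
                f"mismatched record counts: {short} ended before its mate; "
                f"first orphan id {orphan.read_id!r}"  # type: ignore[union-attr]
            )
        yield MatePair(fwd=r1, rev=r2)  # type: ignore[arg-type]


def _record_header(rec) -> str:
    # CompositeRead carries provenance in the description: overlap=<int>
    # conf=<float>; plain reads have a bare id.
    if hasattr(rec, "confidence"):
        return f"{rec.read_id} overlap={rec.overlap_len} conf={rec.confidence:.4f}"
    return rec.read_id


def write_fastq(
    records: Iterable,
    path: PathLikeT,
    encoding: Encoding = Encoding.PHRED33,
) -> int:
    """Write ReadRecords or CompositeReads as 4-line FASTQ; returns the count."""
    if encoding is Encoding.AUTO:
        raise ValueError("write_fastq needs a concrete encoding, not auto")
    off = encoding.offset
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            q = np.asarray(rec.quals, dtype=np.int16)
            if len(q) and (int(q.min()) < 0 or int(q.max()) > QUAL_MAX):
                raise ValueError(
                    f"read {rec.read_id!r}: quality outside encodable range "
                    f"[0, {QUAL_MAX}]"
                )
            qstr = (q + off).astype(np.uint8).tobytes().decode("ascii")
            fh.write(f"@{_record_header(rec)}\n{rec.bases}\n+\n{qstr}\n")
            n += 1
    return n


def read_composites(
    path: PathLikeT, encoding: Encoding = Encoding.PHRED33
) -> Iterator:
    """Read composite reads written by :func:`write_fastq`.

    Parses the ``overlap=<int> conf=<float>`` keys from the description back
    into CompositeRead fields; records without those keys raise.
    """
    from .consensus import CompositeRead
    from .align import Geometry

    if encoding is Encoding.AUTO:
        encoding = detect_encoding(path)
    with _open_text(path) as fh:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh), 1):
            rec = _decode_record(title, seq, qual, encoding, 1, path, i)
            fields = dict(
                kv.split("=", 1) for kv in title.split()[1:] if "=" in kv
            )
            try:
                overlap = int(fields["overlap"])
                conf = float(fields["conf"])
            except KeyError as exc:
                raise FastqFormatError(
                    f"{path} record {i}: missing composite key {exc}"
                ) from None
            geometry = (
                Geometry.READTHROUGH
                if len(seq) == overlap
                else Geometry.NORMAL
            )
            yield CompositeRead(
                read_id=rec.read_id,
                bases=rec.bases,
                quals=rec.quals,
                overlap_len=overlap,
                confidence=conf,
                source_geometry=geometry,
            )
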