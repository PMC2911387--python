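"""Mate-pair read simulator with known truth and per-cycle error profiles.

Emulates a paired-end Illumina run over a (random or supplied) reference:
insert lengths are drawn from a truncated Normal, fragments are placed
uniformly on either strand, and each mate reads the first ``read_len`` bases
of its strand of the insert. Inserts shorter than the read length make the
synthesis run past the fragment end into a fixed adapter sequence
(read-through), exactly the geometry the merger must recognise and trim.

Substitution errors are drawn independently per cycle from a monotone
per-cycle error curve; the erroneous base is uniform over the other three.
Quality strings report the Phred transform of the profile's true per-cycle
error, so simulated qualities are honest by construction and posterior
quality calibration can be tested exactly (a miscalibration offset is
available for robustness experiments). A low-rate single-base deletion
channel (default off) supports indel diagnostics.

Everything is deterministic under the profile's seed. Coordinates in truth
records are 0-based, half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Optional, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fastq import Encoding, MatePair, ReadRecord, write_fastq

#: universal Illumina paired-end adapter prefix seen on read-through
ADAPTER = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAGA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC[_a] = _b

#: shortest insert the simulator will emit
MIN_INSERT = 20


def default_error_profile(
    read_len: int,
    mate: int,
    base_error: float = 0.002,
    tail_error: float = 0.05,
) -> np.ndarray:
    """Monotone per-cycle substitution-error curve for one mate.

    A power-law rise from ``base_error`` at cycle 1 to ``tail_error`` at the
    final cycle, calibrated so the error first exceeds 1% after cycle
    110/143 of the read for mate 1 and 87/143 for mate 2 — the published
    behaviour of the run this simulator emulates.
    """
    if mate not in (1, 2):
        raise ValueError("mate must be 1 or 2")
    if not 0.0 < base_error < 0.01 < tail_error <= 0.75:
        raise ValueError("need base_error < 1% < tail_error <= 0.75")
    if read_len == 1:
        return np.array([base_error])
    frac = (110 if mate == 1 else 87) / 143.0
    brk = min(max(int(round(frac * read_len)), 1), read_len - 1)
    x = np.arange(read_len) / (read_len - 1)
    x_cross = (brk - 0.5) / (read_len - 1)
    gamma = np.log((0.01 - base_error) / (tail_error - base_error)) / np.log(
        x_cross
    )
    profile = base_error + (tail_error - base_error) * x**gamma
    return np.clip(profile, base_error, 0.75)


@dataclass
class SimProfile:
    """Simulator parameterisation (defaults mirror the emulated run)."""

    read_len: int = 143
    insert_mu: float = 180.0
    insert_sigma: float = 40.0
    n_pairs: int = 1000
    gc: float = 0.5
    error_profile_fwd: Optional[np.ndarray] = None
    error_profile_rev: Optional[np.ndarray] = None
    seed: int = 0
    ref_len: int = 100_000
    adapter: str = ADAPTER
    quality_offset: int = 0  # deliberate miscalibration knob, 0 = honest
    indel_rate: float = 0.0  # per-pair 1-bp deletion channel, off by default
    tail_error: float = 0.05

    def profile(self, mate: int) -> np.ndarray:
        given = self.error_profile_fwd if mate == 1 else self.error_profile_rev
        if given is None:
            given = default_error_profile(
                self.read_len, mate, tail_error=self.tail_error
            )
        prof = np.asarray(given, dtype=float)
        if prof.shape != (self.read_len,):
            raise ValueError("error profile length must equal read_len")
        if prof.min() <= 0.0 or prof.max() > 0.75:
            raise ValueError("error probabilities must lie in (0, 0.75]")
        return prof

    def qualities(self, mate: int) -> np.ndarray:
        q = np.rint(-10.0 * np.log10(self.profile(mate))) + self.quality_offset
        return np.clip(q, 0, 60).astype(np.int16)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated pair (0-based, half-open)."""

    pair_id: str
    true_insert_len: int
    ref_start: int
    strand: str
    is_readthrough: bool


def generate_reference(ref_len: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. reference sequence with P(G) = P(C) = gc/2."""
    if ref_len < 1:
        raise ValueError("ref_len must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=ref_len, p=[at, gc / 2.0, gc / 2.0, at])
    return _BASES[codes].tobytes().decode("ascii")


def _sample_inserts(profile: SimProfile, rng: np.random.Generator) -> np.ndarray:
    lo, hi = MIN_INSERT, profile.ref_len
    if profile.insert_sigma == 0:
        ins = np.full(profile.n_pairs, int(round(profile.insert_mu)))
        return np.clip(ins, lo, hi)
    ins = np.empty(profile.n_pairs, dtype=np.int64)
    need = np.arange(profile.n_pairs)
    for _ in range(100):  # truncation by resampling
        draw = np.rint(
            rng.normal(profile.insert_mu, profile.insert_sigma, size=len(need))
        ).astype(np.int64)
        ok = (draw >= lo) & (draw <= hi)
        ins[need[ok]] = draw[ok]
        need = need[~ok]
        if len(need) == 0:
            return ins
    ins[need] = int(np.clip(round(profile.insert_mu), lo, hi))
    return ins


def simulate_pairs(
    profile: SimProfile,
    reference: Optional[str] = None,
) -> tuple[list[MatePair], list[TruthRecord], str]:
    """Simulate mate pairs; returns (pairs, truth records, reference).

    Deterministic under ``profile.seed``: the same profile yields
    byte-identical reads and truth.
    """
    rng = np.random.default_rng(profile.seed)
    if reference is None:
        reference = generate_reference(profile.ref_len, profile.gc, profile.seed)
    ref = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    profile = _with_ref_len(profile, len(ref))
    L = profile.read_len
    n = profile.n_pairs
    adapter = np.frombuffer(profile.adapter.encode("ascii"), dtype=np.uint8)
    if len(adapter) < L:
        adapter = np.tile(adapter, L // len(adapter) + 1)

    inserts = _sample_inserts(profile, rng)
    starts = rng.integers(0, len(ref) - inserts + 1)
    strands = rng.integers(0, 2, size=n)
    deletions = (
        rng.random(n) < profile.indel_rate
        if profile.indel_rate > 0
        else np.zeros(n, dtype=bool)
    )

    m1 = np.empty((n, L), dtype=np.uint8)
    m2 = np.empty((n, L), dtype=np.uint8)
    truths: list[TruthRecord] = []
    for i in range(n):
        ins_len = int(inserts[i])
        seg = ref[starts[i] : starts[i] + ins_len]
        if strands[i]:
            seg = _RC[seg][::-1]
        if deletions[i] and ins_len > MIN_INSERT:
            # drop one interior base: the fragment carries a 1-bp deletion
            # relative to the truth record's insert length
            pos = int(rng.integers(1, ins_len - 1))
            seg = np.delete(seg, pos)
        fwd = seg[:L]
        rev = _RC[seg][::-1][:L]
        if len(seg) < L:
            pad = adapter[: L - len(seg)]
            fwd = np.concatenate([fwd, pad])
            rev = np.concatenate([rev, pad])
        m1[i] = fwd
        m2[i] = rev
        truths.append(
            TruthRecord(
                pair_id=f"sim_{i:06d}",
                true_insert_len=ins_len,
                ref_start=int(starts[i]),
                strand="-" if strands[i] else "+",
                is_readthrough=ins_len < L,
            )
        )

    for mate, arr in ((1, m1), (2, m2)):
        _apply_errors(arr, profile.profile(mate), rng)

    q1, q2 = profile.qualities(1), profile.qualities(2)
    pairs = [
        MatePair(
            fwd=ReadRecord(t.pair_id, m1[i].tobytes().decode("ascii"), q1, mate=1),
            rev=ReadRecord(t.pair_id, m2[i].tobytes().decode("ascii"), q2, mate=2),
        )
        for i, t in enumerate(truths)
    ]
    return pairs, truths, reference


def _with_ref_len(profile: SimProfile, ref_len: int) -> SimProfile:
    if profile.ref_len != ref_len:
        from dataclasses import replace

        profile = replace(profile, ref_len=ref_len)
    if ref_len < MIN_INSERT:
        raise ValueError("reference shorter than the minimum insert")
    return profile


def _apply_errors(
    reads: np.ndarray, profile: np.ndarray, rng: np.random.Generator
) -> None:
    """In-place per-cycle substitutions, uniform over the other three bases."""
    mask = rng.random(reads.shape) < profile[None, :]
    k = int(mask.sum())
    if k == 0:
        return
    idx = _code_of(reads[mask])
    shift = rng.integers(1, 4, size=k)
    reads[mask] = _BASES[(idx + shift) % 4]


def _code_of(ascii_bases: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.int64)
    for i, c in enumerate(b"ACGT"):
        table[c] = i
    return table[ascii_bases]


def clean_reads(
    truth: TruthRecord, reference: str, profile: SimProfile
) -> tuple[str, str]:
    """Error-free (mate1, mate2) sequences implied by a truth record."""
    ref = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    seg = ref[truth.ref_start : truth.ref_start + truth.true_insert_len]
    if truth.strand == "-":
        seg = _RC[seg][::-1]
    L = profile.read_len
    adapter = np.frombuffer(profile.adapter.encode("ascii"), dtype=np.uint8)
    if len(adapter) < L:
        adapter = np.tile(adapter, L // len(adapter) + 1)
    fwd = seg[:L]
    rev = _RC[seg][::-1][:L]
    if len(seg) < L:
        pad = adapter[: L - len(seg)]
        fwd = np.concatenate([fwd, pad])
        rev = np.concatenate([rev, pad])
    return fwd.tobytes().decode("ascii"), rev.tobytes().decode("ascii")


def write_simulation(
    pairs: list[MatePair],
    truths: list[TruthRecord],
    reference: str,
    out_prefix: Union[str, PathLike],
    encoding: Encoding = Encoding.PHRED33,
) -> dict[str, Path]:
    """Write paired FASTQ, truth TSV and reference FASTA; returns the paths."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fastq_1": prefix.with_name(prefix.name + "_1.fastq"),
        "fastq_2": prefix.with_name(prefix.name + "_2.fastq"),
        "truth": prefix.with_name(prefix.name + "_truth.tsv"),
        "reference": prefix.with_name(prefix.name + "_ref.fasta"),
    }
    write_fastq((p.fwd for p in pairs), paths["fastq_1"], encoding)
    write_fastq((p.rev for p in pairs), paths["fastq_2"], encoding)
    with open(paths["truth"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["pair_id", "ref_start", "insert_len", "strand", "is_readthrough"])
        for t in truths:
            w.writerow(
                [t.pair_id, t.ref_start, t.true_insert_len, t.strand,
                 int(t.is_readthrough)]
            )
    SeqIO.write(
        [SeqRecord(Seq(reference), id="sim_ref", description="simulated reference")],
        str(paths["reference"]),
        "fasta",
    )
    return paths


def read_truth(path: Union[str, PathLike]) -> list[TruthRecord]:
    """Read a truth TSV written by :func:`write_simulation`."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                TruthRecord(
                    pair_id=row["pair_id"],
                    true_insert_len=int(row["insert_len"]),
                    ref_start=int(row["ref_start"]),
                    strand=row["strand"],
                    is_readthrough=bool(int(row["is_readthrough"])),
                )
            )
    return out
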