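"""Composite-read construction and posterior base qualities.

For a base position covered by both mates the two calls are treated as
independent observations of the same true insert base. With per-read error
probabilities e_i = 10**(-q_i/10), the observation model is

    P(call b | true x) = 1 - e      if b == x
                       = e / 3      otherwise  (errors uniform over the
                                                other three bases)

and alignment correctness is conditioned to be certain. The posterior over
the four possible true bases is

    P(x | b1, b2) ∝ prior(x) * P(b1 | x) * P(b2 | x)

The consensus base is the agreeing base, the informative base when the other
is N, or the higher-quality call on disagreement (ties go to mate 1); its
reported error is the total posterior mass on the other three bases, and the
composite quality is the Phred transform of that error, rounded and capped
(default Q40).

Two guards keep the arithmetic honest: input qualities of 0-1 imply error
rates at or above random guessing, so e is clamped to <= 0.75 before
enumeration; and positions where only one mate is informative keep that
mate's original quality unchanged (a single observation carries no posterior
update here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np

from .align import CandidateAlignment, Geometry, overlap_span
from .fastq import QUAL_UNINFORMATIVE, MatePair, ReadRecord, reverse_complement

BASES = "ACGT"
#: error probability of a uniform random guess; calls worse than this are
#: anti-informative, which Phred semantics never intend
E_CLAMP = 0.75

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class PriorKind(str, Enum):
    UNIFORM = "uniform"
    GC_BASED = "gc_based"


@dataclass(frozen=True)
class PriorModel:
    """Prior probabilities over the true base {A, C, G, T}."""

    kind: PriorKind
    p: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.p) - 1.0) > 1e-12:
            raise ValueError(f"prior must sum to 1, got {sum(self.p)!r}")
        if min(self.p) <= 0.0:
            raise ValueError("degenerate prior: every base needs mass > 0")

    @classmethod
    def uniform(cls) -> "PriorModel":
        return cls(PriorKind.UNIFORM, (0.25, 0.25, 0.25, 0.25))

    @classmethod
    def gc_based(cls, gc: float) -> "PriorModel":
        if not 0.0 < gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        at = (1.0 - gc) / 2.0
        return cls(PriorKind.GC_BASED, (at, gc / 2.0, gc / 2.0, at))


def estimate_gc_prior(reads: Iterable[ReadRecord], window: int = 50) -> PriorModel:
    """Estimate a GC-based prior from the low-error head of the reads.

    Counts G+C over the first ``window`` cycles of each read (N ignored) —
    the early cycles being the low-error portion of an Illumina read.
    """
    gc = at = 0
    for r in reads:
        head = r.bases[:window]
        gc += head.count("G") + head.count("C")
        at += head.count("A") + head.count("T")
    total = gc + at
    if total == 0:
        raise ValueError("no informative bases to estimate a GC prior from")
    frac = gc / total
    # keep the prior proper even for pathological compositions
    frac = min(max(frac, 1e-6), 1.0 - 1e-6)
    return PriorModel.gc_based(frac)


def error_from_phred(q: float) -> float:
    """Error probability for quality q, clamped to the uninformative bound."""
    return min(10.0 ** (-q / 10.0), E_CLAMP)


def consensus_base(b1: str, q1: int, b2: str, q2: int) -> tuple[str, str]:
    """Consensus call for two overlapped bases; returns (base, rule).

    Rules: ``agree`` (same call), ``n_rescue`` (one call is N, the other
    wins), ``both_n``, ``higher_quality`` (disagreement, larger q wins),
    ``tie_mate1`` (disagreement with q1 == q2, mate 1 wins).
    """
    if b1 == b2:
        return (b1, "both_n") if b1 == "N" else (b1, "agree")
    if b1 == "N":
        return b2, "n_rescue"
    if b2 == "N":
        return b1, "n_rescue"
    if q1 == q2:
        return b1, "tie_mate1"
    return (b1, "higher_quality") if q1 > q2 else (b2, "higher_quality")


def posterior_error(
    b1: str, q1: int, b2: str, q2: int, prior: PriorModel | None = None
) -> float:
    """Posterior probability that the consensus base is wrong.

    Exact Bayesian enumeration over the four possible true bases; both calls
    must be informative (N handling is a pass-through upstream).
    """
    if b1 not in _BASE_INDEX or b2 not in _BASE_INDEX:
        raise ValueError("posterior_error needs informative bases (not N)")
    prior = prior or PriorModel.uniform()
    e1 = error_from_phred(q1)
    e2 = error_from_phred(q2)
    cons, _ = consensus_base(b1, q1, b2, q2)
    total = 0.0
    on_consensus = 0.0
    for x, px in zip(BASES, prior.p):
        like = px
        like *= (1.0 - e1) if b1 == x else e1 / 3.0
        like *= (1.0 - e2) if b2 == x else e2 / 3.0
        total += like
        if x == cons:
            on_consensus = like
    return 1.0 - on_consensus / total


def phred_from_error(e: float, cap: int = 40) -> int:
    """Phred-scale an error probability: round(-10*log10(e)) clamped to [0, cap]."""
    if e <= 0.0:
        raise ValueError("error probability must be > 0")
    q = round(-10.0 * math.log10(min(e, 1.0)))
    return max(0, min(int(q), cap))


@dataclass
class CompositeRead:
    """Merged full-insert sequence with recalculated qualities."""

    read_id: str
    bases: str
    quals: np.ndarray
    overlap_len: int
    confidence: float = float("nan")
    source_geometry: Geometry = Geometry.NORMAL

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError("bases/quals length mismatch")

    def __len__(self) -> int:
        return len(self.bases)


def build_composite(
    pair: MatePair,
    best: CandidateAlignment,
    prior: PriorModel | None = None,
    cap: int = 40,
) -> CompositeRead:
    """Assemble the composite read for the selected alignment.

    Positions covered by one mate copy its base and quality unchanged;
    overlapped positions get the consensus base and posterior quality. In
    read-through geometry only the insert-length region is emitted (bases
    past the mate's far end are adapter and are trimmed).
    """
    prior = prior or PriorModel.uniform()
    rc = reverse_complement(pair.rev)
    len1, len2 = len(pair.fwd), len(rc)
    t = best.offset
    s, e = overlap_span(t, len1, len2)

    bases: list[str] = list(pair.fwd.bases[:s])
    quals: list[int] = [int(q) for q in pair.fwd.quals[:s]]
    for i in range(s, e):
        b1, q1 = pair.fwd.bases[i], int(pair.fwd.quals[i])
        b2, q2 = rc.bases[i - t], int(rc.quals[i - t])
        cons, rule = consensus_base(b1, q1, b2, q2)
        if rule in ("agree", "higher_quality", "tie_mate1"):
            q = phred_from_error(posterior_error(b1, q1, b2, q2, prior), cap)
        elif rule == "n_rescue":
            q = q2 if b1 == "N" else q1
        else:  # both_n
            q = QUAL_UNINFORMATIVE
        bases.append(cons)
        quals.append(q)
    bases.extend(rc.bases[e - t : len2])
    quals.extend(int(q) for q in rc.quals[e - t : len2])

    return CompositeRead(
        read_id=pair.fwd.read_id,
        bases="".join(bases),
        quals=np.array(quals, dtype=np.int16),
        overlap_len=best.overlap_len,
        source_geometry=best.geometry,
    )


def posterior_error_tables(
    prior: PriorModel, qmax: int = 60
) -> np.ndarray:
    """Posterior-error lookup over (base1, base2, q1, q2) for informative calls.

    Vectorised form of :func:`posterior_error` used by the batch engine;
    shape (4, 4, qmax+1, qmax+1).
    """
    e = np.minimum(10.0 ** (-np.arange(qmax + 1) / 10.0), E_CLAMP)
    # like[b, x, q] = P(call b | true x, quality q)
    eye = np.eye(4, dtype=bool)[:, :, None]
    like = np.where(eye, 1.0 - e[None, None, :], e[None, None, :] / 3.0)
    p = np.asarray(prior.p)
    # joint[b1, b2, q1, q2, x]
    joint = (
        p[None, None, None, None, :]
        * like.transpose(0, 2, 1)[:, None, :, None, :]
        * like.transpose(0, 2, 1)[None, :, None, :, :]
    )
    total = joint.sum(axis=-1)
    # consensus index: agreeing base, else the higher-quality call, q-tie -> b1
    b1 = np.arange(4)[:, None, None, None]
    b2 = np.arange(4)[None, :, None, None]
    q1 = np.arange(qmax + 1)[None, None, :, None]
    q2 = np.arange(qmax + 1)[None, None, None, :]
    cons = np.where((b1 == b2) | (q1 >= q2), b1, b2)
    cons = np.broadcast_to(cons, total.shape)
    on_cons = np.take_along_axis(joint, cons[..., None], axis=-1)[..., 0]
    return 1.0 - on_cons / total


def quality_tables(
    prior: PriorModel, cap: int = 40, qmax: int = 60
) -> np.ndarray:
    """Integer composite-quality lookup matching :func:`posterior_error_tables`."""
    err = posterior_error_tables(prior, qmax)
    q = np.rint(-10.0 * np.log10(err))
    return np.clip(q, 0, cap).astype(np.int16)
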