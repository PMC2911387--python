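"""End-to-end merging pipeline: align, build consensus, score confidence.

Two execution paths produce identical results:

* :func:`merge_pair` — the readable per-pair reference path built directly
  from ``align``, ``consensus`` and ``confidence``.
* :func:`merge_pairs` — a batched engine that vectorises candidate scoring,
  best selection, comparator choice and consensus across chunks of pairs
  sharing read lengths. This is what makes multi-million-pair libraries
  tractable; the test suite asserts its equality with the reference path.

Both stream: memory is constant in the number of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .align import (
    Geometry,
    N_ORD,
    candidate_offsets,
    enumerate_candidates,
    overlap_span,
)
from .confidence import MAX_COMPARATORS, ConfidenceResult, alignment_confidence
from .consensus import (
    CompositeRead,
    PriorModel,
    build_composite,
    quality_tables,
)
from .fastq import QUAL_MAX, QUAL_UNINFORMATIVE, MatePair

_RC_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC_TABLE[_a] = _b

_BASE_IDX = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(b"ACGT"):
    _BASE_IDX[_c] = _i


@dataclass
class MergeConfig:
    """All merge-stage parameters with their documented defaults."""

    min_overlap: int = 10
    match_weight: float = 1.0
    mismatch_penalty: float = 1.0
    qual_cap: int = 40
    prior: PriorModel = field(default_factory=PriorModel.uniform)
    conf_threshold: float = 0.5
    baseline_stat: str = "mean"
    conf_range: str = "all"  # or "comparators"

    def quality_table(self) -> np.ndarray:
        if not hasattr(self, "_qtab"):
            self._qtab = quality_tables(self.prior, self.qual_cap, QUAL_MAX)
        return self._qtab


@dataclass
class MergeResult:
    """Outcome for one input pair; composite is None when unmergeable."""

    pair_id: str
    composite: Optional[CompositeRead]
    confidence: Optional[ConfidenceResult]
    best_score: Optional[float] = None

    @property
    def mergeable(self) -> bool:
        return self.composite is not None


def merge_pair(pair: MatePair, config: MergeConfig | None = None) -> MergeResult:
    """Merge a single mate pair (reference implementation)."""
    config = config or MergeConfig()
    scan = enumerate_candidates(
        pair, config.min_overlap, config.match_weight, config.mismatch_penalty
    )
    if not scan.mergeable:
        return MergeResult(pair.fwd.read_id, None, None)
    conf = alignment_confidence(
        scan, MAX_COMPARATORS, config.baseline_stat, config.conf_range
    )
    composite = build_composite(pair, scan.best, config.prior, config.qual_cap)
    composite.confidence = conf.confidence
    return MergeResult(pair.fwd.read_id, composite, conf, scan.best.score)


def merge_pairs(
    pairs: Iterable[MatePair],
    config: MergeConfig | None = None,
    chunk_size: int = 4096,
) -> Iterator[MergeResult]:
    """Merge a stream of pairs with the batched engine, preserving order."""
    config = config or MergeConfig()
    batch: list[MatePair] = []
    for pair in pairs:
        batch.append(pair)
        if len(batch) >= chunk_size:
            yield from _merge_chunk(batch, config)
            batch = []
    if batch:
        yield from _merge_chunk(batch, config)


def _merge_chunk(batch: list[MatePair], config: MergeConfig) -> list[MergeResult]:
    results: list[Optional[MergeResult]] = [None] * len(batch)
    groups: dict[tuple[int, int], list[int]] = {}
    for i, p in enumerate(batch):
        groups.setdefault((len(p.fwd), len(p.rev)), []).append(i)
    for (len1, len2), idx in groups.items():
        n_cand = len(candidate_offsets(len1, len2, config.min_overlap))
        if n_cand == 0:
            for i in idx:
                results[i] = MergeResult(batch[i].fwd.read_id, None, None)
        elif n_cand < MAX_COMPARATORS + 1:
            # tiny candidate lists: the reference path is cheap and already
            # handles the <2-comparator degeneracies
            for i in idx:
                results[i] = merge_pair(batch[i], config)
        else:
            for i, res in zip(idx, _merge_group([batch[i] for i in idx], config)):
                results[i] = res
    return results  # type: ignore[return-value]


def _pack(reads, quals_attr=True) -> tuple[np.ndarray, np.ndarray]:
    bases = np.frombuffer(
        "".join(r.bases for r in reads).encode("ascii"), dtype=np.uint8
    ).reshape(len(reads), -1)
    quals = np.stack([r.quals for r in reads]).astype(np.int16)
    return bases, quals


def _merge_group(group: list[MatePair], config: MergeConfig) -> list[MergeResult]:
    """Vectorised merge of pairs sharing (len1, len2)."""
    n = len(group)
    len1, len2 = len(group[0].fwd), len(group[0].rev)
    F, QF = _pack([p.fwd for p in group])
    R, QR = _pack([p.rev for p in group])
    Rc = _RC_TABLE[R][:, ::-1]
    QRc = QR[:, ::-1]

    offsets = list(candidate_offsets(len1, len2, config.min_overlap))
    spans = [overlap_span(t, len1, len2) for t in offsets]
    lens = np.array([e - s for (s, e) in spans])
    inserts = np.array(offsets) + len2
    is_rt = (inserts < len1) | (inserts < len2)

    # candidate axis ordered so np.argmax's first-max rule reproduces the
    # best-candidate tie-break: larger overlap, then normal geometry, then
    # larger offset
    order = sorted(
        range(len(offsets)),
        key=lambda j: (-lens[j], bool(is_rt[j]), -offsets[j]),
    )
    offsets = [offsets[j] for j in order]
    spans = [spans[j] for j in order]
    lens, inserts, is_rt = lens[order], inserts[order], is_rt[order]
    C = len(offsets)

    n_match = np.empty((n, C), dtype=np.int32)
    n_valid = np.empty((n, C), dtype=np.int32)
    for j, (t, (s, e)) in enumerate(zip(offsets, spans)):
        a = F[:, s:e]
        b = Rc[:, s - t : e - t]
        valid = (a != N_ORD) & (b != N_ORD)
        n_match[:, j] = ((a == b) & valid).sum(axis=1)
        n_valid[:, j] = valid.sum(axis=1)
    n_mismatch = n_valid - n_match
    scores = config.match_weight * n_match - config.mismatch_penalty * n_mismatch

    best_j = np.argmax(scores, axis=1)
    best_score = scores[np.arange(n), best_j]
    best_len = lens[best_j]

    conf, baseline, score_range = _confidence_batch(
        scores, lens, is_rt, np.asarray(offsets), best_j, best_score, best_len,
        len1, len2, config.baseline_stat, config.conf_range,
    )

    results: list[Optional[MergeResult]] = [None] * n
    qtab = config.quality_table()
    for j in np.unique(best_j):
        sub = np.flatnonzero(best_j == j)
        t, (s, e) = offsets[j], spans[j]
        comp_b, comp_q = _consensus_batch(
            F[sub], QF[sub], Rc[sub], QRc[sub], t, s, e, len2, qtab
        )
        geometry = Geometry.READTHROUGH if is_rt[j] else Geometry.NORMAL
        for row, i in enumerate(sub):
            cr = CompositeRead(
                read_id=group[i].fwd.read_id,
                bases=comp_b[row].tobytes().decode("ascii"),
                quals=comp_q[row],
                overlap_len=int(lens[j]),
                confidence=float(conf[i]),
                source_geometry=geometry,
            )
            results[i] = MergeResult(
                cr.read_id,
                cr,
                ConfidenceResult(
                    float(conf[i]),
                    float(baseline[i]),
                    float(score_range[i]),
                    MAX_COMPARATORS,
                ),
                float(best_score[i]),
            )
    return results  # type: ignore[return-value]


def _confidence_batch(
    scores, lens, is_rt, offsets, best_j, best_score, best_len, len1, len2,
    baseline_stat, range_over,
):
    n, C = scores.shape
    lmax = int(lens.max())
    # strict lexicographic (distance, overlap_len, readthrough, offset) as a
    # single integer key, mirroring confidence.comparator_key
    d = np.abs(lens[None, :] - best_len[:, None]).astype(np.int64)
    key = ((d * (lmax + 2) + lens[None, :]) * 2 + is_rt[None, :].astype(np.int64))
    key = key * (len1 + len2 + 2) + (offsets[None, :] + len2)
    key[np.arange(n), best_j] = np.iinfo(np.int64).max  # exclude best
    comp_idx = np.argpartition(key, MAX_COMPARATORS - 1, axis=1)[:, :MAX_COMPARATORS]
    comp_scores = np.take_along_axis(scores, comp_idx, axis=1)
    if baseline_stat == "mean":
        baseline = comp_scores.mean(axis=1)
    elif baseline_stat == "median":
        baseline = np.median(comp_scores, axis=1)
    else:
        raise ValueError(f"unknown baseline statistic {baseline_stat!r}")
    if range_over == "all":
        lo = scores.min(axis=1)
        hi = best_score  # maximal by construction
    elif range_over == "comparators":
        lo = np.minimum(comp_scores.min(axis=1), best_score)
        hi = np.maximum(comp_scores.max(axis=1), best_score)
    else:
        raise ValueError(f"unknown range_over {range_over!r}")
    score_range = (hi - lo).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        conf = np.where(
            score_range > 0, (best_score - baseline) / score_range, 0.0
        )
    return conf, baseline, score_range


def _consensus_batch(F, QF, Rc, QRc, t, s, e, len2, qtab):
    """Composite bases/quals for a sub-group sharing the best offset t."""
    a, b = F[:, s:e], Rc[:, s - t : e - t]
    qa, qb = QF[:, s:e], QRc[:, s - t : e - t]
    ia, ib = _BASE_IDX[a], _BASE_IDX[b]
    a_n, b_n = ia < 0, ib < 0

    # informative-vs-informative: agreeing base or the higher-quality call
    # (q-tie -> mate 1); the quality table encodes the posterior
    take_b = (~a_n) & (~b_n) & (ia != ib) & (qb > qa)
    cons = np.where(take_b, b, a)
    q = qtab[
        np.clip(ia, 0, 3), np.clip(ib, 0, 3),
        np.clip(qa, 0, QUAL_MAX), np.clip(qb, 0, QUAL_MAX),
    ]
    # single-observation positions pass through unchanged
    cons = np.where(a_n & ~b_n, b, cons)
    q = np.where(a_n & ~b_n, qb, q)
    cons = np.where(b_n & ~a_n, a, cons)
    q = np.where(b_n & ~a_n, qa, q)
    both_n = a_n & b_n
    cons = np.where(both_n, np.uint8(N_ORD), cons)
    q = np.where(both_n, np.int16(QUAL_UNINFORMATIVE), q)

    comp_b = np.concatenate([F[:, : max(0, t)], cons, Rc[:, e - t : len2]], axis=1)
    comp_q = np.concatenate(
        [QF[:, : max(0, t)], q, QRc[:, e - t : len2]], axis=1
    ).astype(np.int16)
    return comp_b, comp_q
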