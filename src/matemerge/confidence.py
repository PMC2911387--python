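"""Empirical alignment-confidence metric and composite filtering.

Mis-alignments of similar overlap length have similar alignment scores
(within noise), so the significance of the selected alignment is measured
against its own pair's candidate-score distribution rather than an
analytical model: take the (up to) seven candidates whose overlap length is
nearest the best's, average their scores into a baseline B, and normalise
the best's excess by a score range R:

    C = (best_score - B) / R

By default R spans the scores of the *entire* candidate scan (best minus the
global minimum). This anchors the normaliser at the pair's full score scale,
so a best alignment must stand far above its similar-length baseline to
approach C = 1: well-supported overlaps score 0.7-1.0, while placements that
merely ride the noise of their length class — including most genuine
mis-merges and very short overlaps — fall below 0.5, which is why 0.5 is a
usable default threshold. The alternative ``range_over="comparators"``
restricts R to the comparators plus the best; it keeps C nearer 1 for any
locally-maximal score and needs a correspondingly higher threshold to
discriminate.

Degenerate scans (zero range, fewer than two comparators) get C = 0 — no
evidence of a distinguished optimum. Threshold selection is left to the
user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable

from .align import AlignmentScan

MAX_COMPARATORS = 7


@dataclass(frozen=True)
class ConfidenceResult:
    confidence: float
    baseline: float
    score_range: float
    n_comparators: int


def comparator_key(candidate, best):
    """Deterministic nearness ordering for the comparator set.

    Nearest in overlap length first; distance ties prefer the shorter
    overlap, then normal geometry, then the smaller offset.
    """
    return (
        abs(candidate.overlap_len - best.overlap_len),
        candidate.overlap_len,
        not candidate.is_normal,
        candidate.offset,
    )


def alignment_confidence(
    scan: AlignmentScan,
    max_comparators: int = MAX_COMPARATORS,
    baseline_stat: str = "mean",
    range_over: str = "all",
) -> ConfidenceResult:
    """Score the best alignment against its similar-length comparators.

    ``range_over`` picks the normaliser: ``"all"`` (default) spans every
    candidate score in the scan, ``"comparators"`` only the comparator set
    plus the best.
    """
    if scan.best is None:
        raise ValueError(f"pair {scan.pair_id!r}: empty scan has no confidence")
    best = scan.best
    others = sorted(
        (c for c in scan.candidates if c.offset != best.offset),
        key=lambda c: comparator_key(c, best),
    )
    comparators = others[:max_comparators]
    if len(comparators) < 2:
        return ConfidenceResult(0.0, float("nan"), 0.0, len(comparators))
    scores = [c.score for c in comparators]
    if baseline_stat == "mean":
        baseline = sum(scores) / len(scores)
    elif baseline_stat == "median":
        baseline = float(median(scores))
    else:
        raise ValueError(f"unknown baseline statistic {baseline_stat!r}")
    if range_over == "all":
        lo = min(c.score for c in scan.candidates)
        hi = best.score  # best is maximal by construction
    elif range_over == "comparators":
        lo = min(min(scores), best.score)
        hi = max(max(scores), best.score)
    else:
        raise ValueError(f"unknown range_over {range_over!r}")
    score_range = hi - lo
    if score_range == 0.0:
        return ConfidenceResult(0.0, baseline, 0.0, len(comparators))
    return ConfidenceResult(
        (best.score - baseline) / score_range,
        baseline,
        score_range,
        len(comparators),
    )


def filter_composites(
    reads: Iterable, threshold: float = 0.5
) -> tuple[list, list, float]:
    """Partition composites by confidence >= threshold.

    Returns (kept, rejected, retention); both partitions are preserved —
    composites of all confidence levels remain available downstream.
    """
    if not math.isfinite(threshold) and math.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    kept, rejected = [], []
    for rec in reads:
        (kept if rec.confidence >= threshold else rejected).append(rec)
    total = len(kept) + len(rejected)
    retention = len(kept) / total if total else 0.0
    return kept, rejected, retention
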