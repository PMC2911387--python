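"""Validation accounting: composite-length truth comparison and cost tables.

When the true insert length of each pair is known (simulation, or mapping to
a trusted reference) a merged composite can be audited by its length alone:
a correct ungapped merge reproduces the insert length exactly, small
insertions/deletions in the reads shift it by 1-2 bp, and a wrong overlap
placement shifts it by more. The signed length-difference histogram is
therefore a sum of a sharp small-indel peak around zero and a broad
misalignment distribution; a window rule (|diff| <= indel_window, default 2)
separates the two classes.

The cost table reproduces run-economics arithmetic (reads per dollar, bp per
dollar, cost ratios between two strategies) with half-up integer display
rounding.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .confidence import filter_composites
from .consensus import CompositeRead
from .fastq import MatePair
from .pipeline import MergeConfig, merge_pairs
from .simulate import TruthRecord


@dataclass
class EvalSummary:
    """Retention / misalignment accounting for one validation run."""

    n_input_pairs: int
    n_merged: int
    n_kept: int
    retention: float
    n_correct: int
    n_indel_like: int
    n_misaligned_kept: int
    misalignment_rate: float
    length_diff_histogram: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "n_input_pairs": self.n_input_pairs,
            "n_merged": self.n_merged,
            "n_kept": self.n_kept,
            "retention": self.retention,
            "n_correct": self.n_correct,
            "n_indel_like": self.n_indel_like,
            "n_misaligned_kept": self.n_misaligned_kept,
            "misalignment_rate": self.misalignment_rate,
            "length_diff_histogram": {
                str(k): v for k, v in sorted(self.length_diff_histogram.items())
            },
        }


def length_difference_histogram(
    composites: Iterable[CompositeRead],
    truth: Mapping[str, TruthRecord] | Sequence[TruthRecord],
) -> dict[int, int]:
    """Histogram of (composite length - true insert length), signed."""
    if not isinstance(truth, Mapping):
        truth = {t.pair_id: t for t in truth}
    hist: Counter[int] = Counter()
    for c in composites:
        if c.read_id not in truth:
            raise KeyError(f"composite {c.read_id!r} missing from the truth table")
        hist[len(c) - truth[c.read_id].true_insert_len] += 1
    return dict(hist)


def classify_differences(
    histogram: Mapping[int, int], indel_window: int = 2
) -> tuple[int, int, int]:
    """Split the histogram into (n_correct, n_indel_like, n_misaligned).

    diff == 0 is correct; 1 <= |diff| <= indel_window is indel-like;
    anything larger is a misalignment.
    """
    if indel_window < 0:
        raise ValueError("indel_window must be >= 0")
    n_correct = n_indel = n_mis = 0
    for diff, count in histogram.items():
        if diff == 0:
            n_correct += count
        elif abs(diff) <= indel_window:
            n_indel += count
        else:
            n_mis += count
    return n_correct, n_indel, n_mis


def run_validation(
    pairs: Iterable[MatePair],
    truths: Sequence[TruthRecord],
    config: Optional[MergeConfig] = None,
    conf_threshold: Optional[float] = None,
    indel_window: int = 2,
) -> EvalSummary:
    """Merge, filter, and audit a truth-annotated library end to end."""
    config = config or MergeConfig()
    if conf_threshold is None:
        conf_threshold = config.conf_threshold
    truth_map = {t.pair_id: t for t in truths}

    n_input = 0
    merged: list[CompositeRead] = []
    for res in merge_pairs(pairs, config):
        n_input += 1
        if res.composite is not None:
            merged.append(res.composite)
    kept, _, retention = filter_composites(merged, conf_threshold)
    return summarize_kept(kept, truth_map, n_input, len(merged), indel_window)


def summarize_kept(
    kept: Sequence[CompositeRead],
    truth_map: Mapping[str, TruthRecord],
    n_input: int,
    n_merged: int,
    indel_window: int = 2,
) -> EvalSummary:
    hist = length_difference_histogram(kept, truth_map)
    n_correct, n_indel, n_mis = classify_differences(hist, indel_window)
    n_kept = len(kept)
    return EvalSummary(
        n_input_pairs=n_input,
        n_merged=n_merged,
        n_kept=n_kept,
        retention=n_kept / n_merged if n_merged else 0.0,
        n_correct=n_correct,
        n_indel_like=n_indel,
        n_misaligned_kept=n_mis,
        misalignment_rate=n_mis / n_kept if n_kept else 0.0,
        length_diff_histogram=hist,
    )


# ---------------------------------------------------------------------------
# cost arithmetic


@dataclass(frozen=True)
class CostInputs:
    """One sequencing strategy's run economics."""

    label: str
    run_cost: float
    n_reads: int
    mean_read_len: float

    def __post_init__(self) -> None:
        if self.run_cost <= 0:
            raise ValueError("run cost must be positive")
        if self.n_reads <= 0 or self.mean_read_len <= 0:
            raise ValueError("read count and length must be positive")

    @property
    def reads_per_dollar(self) -> float:
        return self.n_reads / self.run_cost

    @property
    def bp_per_dollar(self) -> float:
        return self.n_reads * self.mean_read_len / self.run_cost


def round_half_up(x: float) -> int:
    """Display rounding: half-up to integer (2380.95 -> 2381, 47.5 -> 48)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), ROUND_HALF_UP))


def cost_metrics(a: CostInputs, b: CostInputs) -> pd.DataFrame:
    """Side-by-side cost comparison of two strategies.

    Derived rows are computed on unrounded values and displayed with half-up
    integer rounding; ratios are expressed relative to strategy ``b``.
    """
    rows = {
        "Cost of a run ($)": (a.run_cost, b.run_cost),
        "Number of reads obtained": (a.n_reads, b.n_reads),
        "Average read length (bp)": (a.mean_read_len, b.mean_read_len),
        "Reads per $": (
            round_half_up(a.reads_per_dollar),
            round_half_up(b.reads_per_dollar),
        ),
        "bp per $": (
            round_half_up(a.bp_per_dollar),
            round_half_up(b.bp_per_dollar),
        ),
        "Cost ratio per read": (
            round_half_up(a.reads_per_dollar / b.reads_per_dollar),
            1,
        ),
        "Cost ratio per bp": (
            round_half_up(a.bp_per_dollar / b.bp_per_dollar),
            1,
        ),
    }
    # object dtype keeps the display-rounded integers printing as integers
    return pd.DataFrame(rows, index=[a.label, b.label], dtype=object).T
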