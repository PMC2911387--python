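# Methods

This note documents the statistical model, the defaults and why they are
what they are, what the simulator does and does not emulate, and the design
choices made where the design was genuinely open.

## Overlap alignment

Both mates are expressed on the insert's forward strand (mate 2 is
reverse-complemented), and every ungapped placement is parameterised by the
signed offset `t` of mate 2 relative to mate 1; the implied insert length is
`t + len2`. All placements with string overlap in `[min_overlap,
min(len1, len2)]` are enumerated — `len1 + len2 − 2·min_overlap + 1`
candidates for equal-length reads — covering the normal geometry (insert at
least a read length) and the read-through geometry (insert shorter than a
read, where each mate sequences through the fragment into adapter; the
composite is the insert region only, adapter bases are trimmed).

Scoring is `matches − penalty·mismatches` with `match_weight =
mismatch_penalty = 1`. The symmetric default makes the score read as
`overlap − 2·mismatches`; the magnitude is immaterial downstream because
the confidence metric is invariant to scaling both weights. Positions with
`N` in either read count as neither match nor mismatch (no information).
Base qualities deliberately play no role in alignment scoring; they enter
only at the consensus stage. Ties on score prefer the larger overlap (more
evidence), then normal geometry, then the larger offset — the last rule
exists only to make unequal-length inputs fully deterministic.

`min_overlap` defaults to 10 bp. It bounds the enumeration and the
false-positive surface; pairs with no candidate at that floor are flagged
unmergeable and reported separately, never silently dropped.

## Consensus and posterior quality

At an overlapped position the two calls are modelled as independent
observations of the true insert base, with a miscall uniform over the other
three bases and alignment correctness conditioned to be certain:

    P(x | b1, b2) ∝ prior(x) · P(b1 | x) · P(b2 | x)
    P(b | x) = 1 − e  if b = x,  else e/3,   e = 10^(−q/10)

The consensus call is the agreeing base, the informative base when the
other is `N`, or the higher-quality call on disagreement (a quality tie
goes to mate 1 — a documented arbitrary rule). The reported quality is
`round(−10·log10(posterior error))`, clamped to `[0, qual_cap]`.

Numerical choices:

* **`qual_cap = 40`.** Two agreeing tail bases can compound to Q45+;
  empirical calibration of composite qualities against real references is
  known to saturate in the low 30s (reference imperfection, residual
  indels), so unbounded scores would overstate certainty. Q40 keeps scores
  honest and encodable; `--qual-cap` exposes it.
* **Error clamp at 0.75.** `q ≤ 1` implies an error rate at or beyond
  uniform guessing; such a call is anti-informative under the model, which
  Phred semantics never intend. `e` is clamped to 0.75, at which the
  observation carries exactly zero information and the posterior collapses
  to the other read's error rate. (Consequence: the "agreement always
  improves quality" property holds strictly for q ≥ 2 and degrades to
  equality at the clamp.)
* **Single-observation positions pass through unchanged** (one mate `N`,
  or outside the overlap): a lone observation warrants no posterior update.
  Double-`N` positions emit `N` at quality 2.
* **Prior.** Uniform by default — appropriate for mixed-community
  (metagenomic) input where no single base composition applies. A GC-based
  prior can be estimated from the low-error portion of the reads,
  operationalised as the first 50 cycles of mate 1 (`--gc-window`), for
  single-genome libraries.

The batch engine evaluates the same posterior through a precomputed
`(4, 4, 61, 61)` lookup table; the test suite pins both the scalar path and
the table to an independently written brute-force enumeration at 1e-12.

## Alignment confidence

Short overlaps of non-uniform composition defeat analytical significance
models, so confidence is empirical, computed from the pair's own candidate
scan: mis-placements of similar overlap length score similarly (within
noise), so the baseline `B` is the mean score of the (up to) seven
candidates nearest the best in overlap length, and

    C = (best − B) / R.

**The normaliser `R` spans the full candidate scan** (best minus the global
minimum score). This was the one genuinely open design point, and the
choice is load-bearing: if `R` is instead taken only over the comparators
plus the best (available as `conf_range="comparators"`), *any* locally
maximal score — including pure noise maxima of mis-aligned pairs — lands at
C ≈ 0.5–0.9, and a 0.5 threshold separates nothing (measured on simulated
libraries: retention ≈ 100%, all mis-merges kept). Anchored to the full
score range, genuine overlaps score 0.7–1.0, noise maxima 0.05–0.25, and
0.5 becomes a meaningful operating point: on the default simulated library
it retains ~93% of merges and removes effectively all mis-merges, while
rejecting the long-insert pairs whose short overlaps cannot be
distinguished from noise. The cost is that confidence grows with overlap
length — an error-free overlap needs roughly 50 bp to clear 0.5 — which is
exactly the behaviour that makes the filter conservative where evidence is
thin.

Degenerate cases score 0: zero range (all candidates equal) and scans with
fewer than two comparators — no evidence of a distinguished optimum, so any
positive threshold rejects. The baseline statistic is configurable
(`median` available); `C ≤ 1` always, and `C` is invariant under scaling
the alignment weights.

## Simulator

The simulator emulates a paired-end run over a random (or supplied)
reference:

* **Reference**: i.i.d. bases, `P(G) = P(C) = gc/2`; default 100 kb,
  GC 0.5.
* **Inserts**: truncated Normal, default 180 ± 40 bp on `[20, ref_len]`,
  rounded to integers — the composite-length distribution of the emulated
  run. Fragments are placed uniformly, strand uniform.
* **Reads**: each mate reads the first `read_len` (143) bases of its strand
  of the insert; shorter inserts run into a fixed 34-mer adapter
  (the universal Illumina paired-end adapter prefix), giving read-through
  pairs with known truth.
* **Errors**: independent per-cycle substitutions, the erroneous base
  uniform over the other three. The default per-cycle curve is a power-law
  rise from 0.2% (cycle 1) to 5% (final cycle), calibrated so error first
  exceeds 1% after cycle 110 (mate 1) and 87 (mate 2) — the printed
  behaviour of the emulated run. The published summaries pin only those
  crossings and qualitative tail growth; the power-law form and the 0.2%/5%
  endpoints are this package's choices, fixed once.
* **Qualities are honest**: the quality string is the Phred transform of
  the profile's true per-cycle error, so posterior-quality calibration is
  testable exactly. A `quality_offset` knob deliberately miscalibrates for
  robustness experiments.
* **Indels**: off by default (substitution-only model). An optional
  per-pair single-base deletion channel supports reproducing the
  indel peak in length-difference histograms.

Everything is deterministic under the profile seed, byte-identical across
runs.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: context-dependent and correlated errors
(homopolymer indels, GGC motifs), quality miscalibration, optical
duplicates, chimeric fragments, adapter sequence variants, and repetitive
reference structure. Real libraries also have broader, skewed insert
distributions; since the confidence filter's rejection mass sits in the
long-insert tail, retention on real data depends directly on that
distribution (see Limitations).

## Evaluation harness

With truth available, a merge is audited by composite length alone: exact
recovery gives length difference 0, small read indels shift it by 1–2 bp,
and a misplaced overlap shifts it further. The signed histogram is
decomposed by a window rule: `|diff| ≤ indel_window` (default 2 bp) is
indel-like, larger is a mis-merge. The window rule replaces a model-based
peak decomposition deliberately: it is transparent, conservative, and with
the substitution-only simulator the indel class is empty anyway. Retention
is reported over successfully merged pairs, with unmergeable pairs counted
separately (both denominators are emitted).

The cost table computes reads/$ and bp/$ from (run cost, read count, mean
length) for two strategies plus their ratios, rounding half-up to integers
for display while deriving ratios from unrounded values.

## Problem sizes

The validation script merges a 50,000-pair library for its headline
numbers plus three 5,000-pair replicates; the batched engine processes
~7,000 pairs/s/core at 143 bp, so the full run is seconds, and the same
scale is used in the test suite. Calibration checks use 10,000 pairs —
enough for 3-SE binomial resolution of a 0.2% per-cycle error.

## Known limitations

* Ungapped alignment only: a read indel inside the overlap mis-registers
  part of the consensus; such pairs are detectable downstream (length
  histogram) but not corrected.
* Confidence requires ~50 bp of overlap to clear the default threshold;
  libraries tuned for marginal overlaps should lower the threshold and
  accept more mis-merges, or raise `min_overlap`.
* Retention figures from simulation transfer to real libraries only to the
  extent the insert-length distribution does; the filter rejects the
  long-insert tail, so a broader real distribution retains less.
* The posterior conditions on correct alignment (probability 1); residual
  mis-alignment probability is not folded into base qualities.
* No id-based mate rescue: inputs must be order-matched FASTQ.
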