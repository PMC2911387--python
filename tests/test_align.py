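"""Ungapped overlap enumeration, scoring, and best-candidate selection."""

import numpy as np
import pytest

from matemerge import (
    AlignmentScan,
    CandidateAlignment,
    Geometry,
    MatePair,
    enumerate_candidates,
    reverse_complement,
    select_best,
)

from conftest import make_read, pair_from_insert, random_seq


def pair_with_rc(fwd: str, rc_of_mate2: str) -> MatePair:
    """Build a pair whose reverse-complemented mate 2 equals rc_of_mate2."""
    mate2 = reverse_complement(make_read(rc_of_mate2, mate=2))
    return MatePair(fwd=make_read(fwd, mate=1), rev=mate2)


def brute_force_candidates(fwd: str, rc2: str, min_overlap: int):
    """Independent enumeration by plain string slicing over all offsets."""
    out = []
    L1, L2 = len(fwd), len(rc2)
    for t in range(-L2 + 1, L1):
        s, e = max(0, t), min(L1, t + L2)
        if e - s < min_overlap:
            continue
        a, b = fwd[s:e], rc2[s - t : e - t]
        nm = sum(
            x == y and x != "N" for x, y in zip(a, b)
        )
        nx = sum(
            x != y and x != "N" and y != "N" for x, y in zip(a, b)
        )
        out.append((t, e - s, nm, nx))
    return out


class TestEnumeration:
    def test_eight_mer_example(self):
        # "TACGT" in the tail of mate 1 pairs with "TACGT" at the head of
        # rc(mate 2): overlap 5, five matches, no mismatch
        pair = pair_with_rc("ACGTACGT", "TACGTGGG")
        scan = enumerate_candidates(pair, min_overlap=5)
        hit = [c for c in scan.candidates if c.offset == 3]
        assert len(hit) == 1
        c = hit[0]
        assert (c.overlap_len, c.n_match, c.n_mismatch, c.score) == (5, 5, 0, 5.0)

    def test_identical_reads_full_overlap(self):
        pair = pair_with_rc("ACGTACGTGA", "ACGTACGTGA")
        scan = enumerate_candidates(pair, min_overlap=4, match_weight=2.0)
        full = [c for c in scan.candidates if c.overlap_len == 10]
        assert len(full) == 1
        assert full[0].score == 20.0
        assert scan.best == full[0]

    def test_all_n_read_scores_zero_everywhere(self):
        pair = pair_with_rc("N" * 12, "ACGTACGTACGT")
        scan = enumerate_candidates(pair, min_overlap=3)
        assert all(
            c.n_match == 0 and c.n_mismatch == 0 and c.score == 0.0
            for c in scan.candidates
        )

    @pytest.mark.parametrize("l1,l2,m", [(8, 8, 3), (10, 6, 2), (5, 9, 4), (7, 7, 7)])
    def test_exhaustive_against_brute_force(self, l1, l2, m):
        rng = np.random.default_rng(l1 * 100 + l2 * 10 + m)
        fwd, rc2 = random_seq(rng, l1), random_seq(rng, l2)
        pair = pair_with_rc(fwd, rc2)
        scan = enumerate_candidates(pair, min_overlap=m)
        expected = brute_force_candidates(fwd, rc2, m)
        assert len(scan.candidates) == len(expected)
        got = {(c.offset, c.overlap_len, c.n_match, c.n_mismatch) for c in scan.candidates}
        assert got == set(expected)

    def test_candidate_count_equal_lengths(self):
        pair = pair_with_rc(random_seq(np.random.default_rng(0), 20),
                            random_seq(np.random.default_rng(1), 20))
        scan = enumerate_candidates(pair, min_overlap=5)
        assert len(scan.candidates) == 2 * (20 - 5) + 1

    def test_unmergeable_pair_is_flagged_not_raised(self):
        pair = pair_with_rc("ACGT", "ACGT")
        scan = enumerate_candidates(pair, min_overlap=10)
        assert not scan.mergeable
        assert scan.best is None
        with pytest.raises(ValueError):
            select_best(scan)

    def test_implied_insert_length_identity(self):
        rng = np.random.default_rng(5)
        pair = pair_with_rc(random_seq(rng, 15), random_seq(rng, 15))
        scan = enumerate_candidates(pair, min_overlap=3)
        for c in scan.candidates:
            if c.geometry is Geometry.NORMAL:
                assert c.insert_len == 15 + 15 - c.overlap_len
            else:
                assert c.insert_len == c.overlap_len
                assert c.insert_len < 15


def mk(score, overlap, geometry=Geometry.NORMAL, offset=0):
    return CandidateAlignment(
        offset=offset,
        overlap_len=overlap,
        geometry=geometry,
        n_match=max(int(score), 0),
        n_mismatch=0,
        score=float(score),
        insert_len=overlap,
    )


class TestSelectBest:
    def test_higher_score_wins(self):
        scan = AlignmentScan("p", [mk(3, 8, offset=1), mk(5, 4, offset=2)])
        assert select_best(scan).score == 5.0

    def test_score_tie_prefers_longer_overlap(self):
        scan = AlignmentScan("p", [mk(5, 5, offset=1), mk(5, 7, offset=2)])
        assert select_best(scan).overlap_len == 7

    def test_full_tie_prefers_normal_geometry(self):
        scan = AlignmentScan(
            "p",
            [mk(5, 7, Geometry.READTHROUGH, offset=1), mk(5, 7, Geometry.NORMAL, offset=2)],
        )
        assert select_best(scan).geometry is Geometry.NORMAL

    def test_error_free_pair_recovers_true_overlap(self):
        rng = np.random.default_rng(11)
        insert = random_seq(rng, 180)
        pair = pair_from_insert(insert, read_len=100)
        scan = enumerate_candidates(pair, min_overlap=10)
        assert scan.best.overlap_len == 2 * 100 - 180
        assert scan.best.n_mismatch == 0
        assert scan.best.insert_len == 180

    @pytest.mark.parametrize("insert_len", [160, 200, 250, 100, 80])
    def test_true_placement_is_unique_maximum(self, insert_len):
        # error-free non-repetitive inserts with >= 15 bp overlap: the true
        # placement's score should be the strict maximum
        rng = np.random.default_rng(insert_len)
        for _ in range(5):
            insert = random_seq(rng, insert_len)
            pair = pair_from_insert(insert, read_len=143)
            scan = enumerate_candidates(pair)
            best = scan.best
            assert best.insert_len == insert_len
            runner_up = max(
                c.score for c in scan.candidates if c.offset != best.offset
            )
            assert best.score > runner_up
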