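"""Consensus base calls and posterior quality against a brute-force oracle."""

import math

import numpy as np
import pytest

from matemerge import (
    MatePair,
    PriorModel,
    build_composite,
    consensus_base,
    enumerate_candidates,
    estimate_gc_prior,
    phred_from_error,
    posterior_error,
)
from matemerge.consensus import quality_tables

from conftest import make_read, pair_from_insert


def oracle_posterior(b1, q1, b2, q2, prior_p):
    """Independent enumeration of the consensus-error posterior.

    Deliberately written from scratch: explicit loops, no shared helpers
    with the implementation beyond the stated model (errors uniform over the
    other three bases, observations independent given the true base, e
    clamped at the random-guess rate 0.75).
    """
    e1 = min(10 ** (-q1 / 10), 0.75)
    e2 = min(10 ** (-q2 / 10), 0.75)
    # consensus rule: agreement, else higher quality, q-tie -> mate 1
    if b1 == b2 or q1 >= q2:
        cons = b1
    else:
        cons = b2
    posts = {}
    for x, px in zip("ACGT", prior_p):
        p = px
        p *= (1 - e1) if x == b1 else e1 / 3
        p *= (1 - e2) if x == b2 else e2 / 3
        posts[x] = p
    z = sum(posts.values())
    return sum(v for x, v in posts.items() if x != cons) / z


PRIORS = [PriorModel.uniform(), PriorModel.gc_based(0.62)]


class TestPosteriorError:
    def test_agreement_q20_matches_closed_form(self):
        e = 0.01
        expected = (e**2 / 3) / ((1 - e) ** 2 + e**2 / 3)
        got = posterior_error("A", 20, "A", 20)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(3.40e-5, rel=5e-3)
        assert -10 * math.log10(got) == pytest.approx(44.7, abs=0.05)

    def test_symmetric_disagreement_is_half(self):
        assert posterior_error("C", 30, "T", 30) == pytest.approx(0.5, abs=1e-3)

    def test_q0_clamp_makes_observation_uninformative(self):
        # e(q<=1) clamps to 0.75 = the random-guess rate, at which the second
        # observation carries zero information: the posterior equals the
        # better read's own error rate; any q >= 2 strictly improves it
        for q1 in (10, 20, 35):
            e1 = 10 ** (-q1 / 10)
            assert posterior_error("G", q1, "G", 0) == pytest.approx(e1, abs=1e-12)
            assert posterior_error("G", q1, "G", 2) < e1

    @pytest.mark.parametrize("prior", PRIORS, ids=["uniform", "gc"])
    def test_matches_oracle_on_grid(self, prior):
        qs = [2, 3, 7, 14, 20, 27, 33, 41]
        for b1 in "ACGT":
            for b2 in "ACGT":
                for q1 in qs:
                    for q2 in qs:
                        got = posterior_error(b1, q1, b2, q2, prior)
                        want = oracle_posterior(b1, q1, b2, q2, prior.p)
                        assert abs(got - want) < 1e-12, (b1, q1, b2, q2)

    def test_agreement_beats_both_inputs(self):
        # two agreeing observations: posterior error strictly below both
        # single-read error rates, for every quality combination
        for q1 in range(2, 42):
            for q2 in range(2, 42):
                e = posterior_error("T", q1, "T", q2)
                assert e < min(10 ** (-q1 / 10), 10 ** (-q2 / 10))

    def test_disagreement_decreases_with_quality_gap(self):
        prev = 1.0
        for gap in range(0, 30, 3):
            e = posterior_error("A", 30 + gap // 2, "C", 30 - (gap - gap // 2))
            assert e <= prev + 1e-15
            prev = e

    def test_n_input_rejected(self):
        with pytest.raises(ValueError):
            posterior_error("N", 20, "A", 20)

    def test_table_matches_scalar_path(self):
        prior = PriorModel.gc_based(0.4)
        tab = quality_tables(prior, cap=40)
        rng = np.random.default_rng(3)
        for _ in range(200):
            i, j = rng.integers(0, 4, size=2)
            q1, q2 = (int(x) for x in rng.integers(0, 61, size=2))
            b1, b2 = "ACGT"[i], "ACGT"[j]
            want = phred_from_error(posterior_error(b1, q1, b2, q2, prior), 40)
            assert tab[i, j, q1, q2] == want


class TestConsensusBase:
    @pytest.mark.parametrize(
        "b1,q1,b2,q2,base,rule",
        [
            ("A", 30, "A", 20, "A", "agree"),
            ("N", 2, "G", 25, "G", "n_rescue"),
            ("G", 25, "N", 2, "G", "n_rescue"),
            ("C", 30, "T", 10, "C", "higher_quality"),
            ("C", 10, "T", 30, "T", "higher_quality"),
            ("C", 30, "T", 30, "C", "tie_mate1"),
            ("N", 2, "N", 2, "N", "both_n"),
        ],
    )
    def test_rules(self, b1, q1, b2, q2, base, rule):
        assert consensus_base(b1, q1, b2, q2) == (base, rule)


class TestPhredFromError:
    def test_definition_and_cap(self):
        assert phred_from_error(0.001) == 30
        assert phred_from_error(3.4e-5, cap=40) == 40  # 44.7 capped
        assert phred_from_error(3.4e-5, cap=60) == 45
        assert phred_from_error(1.0) == 0

    def test_nonpositive_error_raises(self):
        with pytest.raises(ValueError):
            phred_from_error(0.0)


class TestPriors:
    def test_gc_prior_composition(self):
        p = PriorModel.gc_based(0.6)
        assert p.p == (0.2, 0.3, 0.3, 0.2)

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ValueError):
            PriorModel("uniform", (0.5, 0.5, 0.0, 0.0))
        with pytest.raises(ValueError):
            PriorModel("uniform", (0.5, 0.2, 0.2, 0.2))

    def test_estimate_gc_uses_leading_window(self):
        reads = [make_read("GGGG" + "AAAA"), make_read("CCCC" + "TTTT")]
        prior = estimate_gc_prior(reads, window=4)
        assert prior.p[1] + prior.p[2] == pytest.approx(1.0, abs=1e-5)
        prior_full = estimate_gc_prior(reads, window=8)
        assert prior_full.p[1] + prior_full.p[2] == pytest.approx(0.5)


class TestBuildComposite:
    def test_identical_mates_fully_overlapped_gain_quality(self):
        pair = pair_from_insert("ACGTTGCAGGTA", read_len=12, quals=20)
        scan = enumerate_candidates(pair, min_overlap=4)
        comp = build_composite(pair, scan.best)
        assert comp.bases == "ACGTTGCAGGTA"
        assert (comp.quals > 20).all()

    def test_normal_geometry_length_arithmetic(self):
        rng = np.random.default_rng(9)
        insert = "".join(rng.choice(list("ACGT"), size=266))
        pair = pair_from_insert(insert, read_len=143)
        scan = enumerate_candidates(pair)
        assert scan.best.overlap_len == 20
        comp = build_composite(pair, scan.best)
        assert len(comp) == 266
        assert comp.bases == insert

    def test_readthrough_trims_adapter(self):
        rng = np.random.default_rng(10)
        insert = "".join(rng.choice(list("ACGT"), size=60))
        pair = pair_from_insert(insert, read_len=100)
        scan = enumerate_candidates(pair)
        comp = build_composite(pair, scan.best)
        assert len(comp) == 60
        assert comp.bases == insert
        assert comp.source_geometry.value == "readthrough"

    def test_n_position_passes_through_informative_base(self):
        insert = "ACGTTGCAGGTA"
        pair = pair_from_insert(insert, read_len=12, quals=25)
        bases = list(pair.fwd.bases)
        bases[5] = "N"
        pair.fwd.bases = "".join(bases)
        scan = enumerate_candidates(pair, min_overlap=4)
        comp = build_composite(pair, scan.best)
        assert comp.bases == insert
        assert comp.quals[5] == 25  # single observation: original quality
        assert (comp.quals[np.arange(12) != 5] > 25).all()

    def test_unoverlapped_positions_keep_original_quality(self):
        rng = np.random.default_rng(12)
        insert = "".join(rng.choice(list("ACGT"), size=40))
        q1 = rng.integers(5, 40, size=30)
        q2 = rng.integers(5, 40, size=30)
        pair = pair_from_insert(insert, read_len=30)
        pair.fwd.quals = q1.astype(np.int16)
        pair.rev.quals = q2.astype(np.int16)
        scan = enumerate_candidates(pair)
        comp = build_composite(pair, scan.best)
        # first 10 bases: mate-1 only; last 10: mate-2 only (reversed quals)
        assert comp.quals[:10].tolist() == q1[:10].tolist()
        assert comp.quals[-10:].tolist() == q2[9::-1].tolist()
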