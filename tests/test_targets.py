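"""Complementarity expectation scoring, transcript scanning and UPE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canemir.data import target_examples
from canemir.records import SequenceRecord, revcomp
from canemir.targets import (
    GU,
    MATCH,
    MISMATCH,
    ScoreScheme,
    expectation_score,
    pair_class,
    scan_transcripts,
    upe_approx,
)

rna = st.text(alphabet="ACGU", min_size=18, max_size=22)

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def naive_window_score(mirna, window):
    """Independent per-position scorer for the default scheme."""
    total = 0.0
    for i, base in enumerate(mirna):
        t = window[len(window) - 1 - i]
        if _COMP[base] == t:
            continue
        if (base, t) in (("G", "U"), ("U", "G")):
            total += 0.5
        else:
            total += 1.0
    return total


class TestPairClass:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("G", "C", MATCH), ("A", "U", MATCH), ("G", "U", GU), ("U", "G", GU),
         ("A", "G", MISMATCH), ("N", "A", MISMATCH)],
    )
    def test_classes(self, a, b, expected):
        assert pair_class(a, b) == expected


class TestExpectationScore:
    def test_bundled_worked_examples_reproduce_exactly(self):
        """Every internally consistent bundled alignment example scores to
        its reported expectation under the default scheme."""
        df = target_examples()
        clean = df[df["clean"] == 1]
        assert len(clean) == 5
        for _, row in clean.iterrows():
            score, _ = expectation_score(row.mirna_fragment, row.target_fragment)
            assert score == row.expectation, row.mirna

    @given(rna)
    def test_perfect_reverse_complement_scores_zero(self, mirna):
        score, labels = expectation_score(mirna, revcomp(mirna))
        assert score == 0.0
        assert set(labels) == {MATCH}

    @given(rna)
    def test_score_invariant_under_fragment_swap(self, mirna):
        """Swapping the two fragments describes the same physical duplex read
        from the other strand, so every pair keeps its class (G:U stays G:U)
        and the score is unchanged under a position-uniform scheme."""
        rng = np.random.default_rng(len(mirna))
        target = "".join(
            np.array(list("ACGU"))[rng.integers(0, 4, len(mirna))]
        )
        s1, _ = expectation_score(mirna, target)
        s2, _ = expectation_score(target, mirna)
        assert s1 == s2

    def test_additivity_over_positions(self):
        m, t = "GGGAAA", "UUUCCC"
        s, labels = expectation_score(m, t)
        per_pos = [0.0 if l == MATCH else (0.5 if l == GU else 1.0) for l in labels]
        assert s == sum(per_pos)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            expectation_score("ACGU", "ACG")

    def test_seed_multiplier_weighs_seed_positions(self):
        scheme = ScoreScheme(seed_interval=(2, 7), seed_multiplier=2.0)
        m = "AAAAAAAAAA"
        t = "AAAAAAAAAA"  # all mismatches (A opposite A)
        base, _ = expectation_score(m, t)
        weighted, _ = expectation_score(m, t, scheme)
        assert base == 10.0
        assert weighted == 16.0  # positions 2-7 doubled


class TestScan:
    def test_planted_perfect_site_found(self):
        mirna = SequenceRecord("m", "UGCCUGGCUCCCUGUAUGCC")
        rng = np.random.default_rng(0)
        pad = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 60)])
        tx = [SequenceRecord("t1", pad + revcomp(mirna.sequence) + pad)]
        hits = scan_transcripts(mirna, tx)
        best = hits[0]
        assert best.expectation == 0.0
        assert best.site.start1 == 61
        assert best.site.end1 == 60 + len(mirna.sequence)
        assert best.target_fragment == revcomp(mirna.sequence)

    def test_planted_gu_plus_mismatch_scores_1_5(self):
        mirna = SequenceRecord("m", "UGCCUGGCUCCCUGUAUGCC")
        site = list(revcomp(mirna.sequence))
        # miRNA position 1 is G: put U opposite (wobble); position 3 is C: put A (mismatch)
        site[len(site) - 2] = "U"
        site[len(site) - 4] = "A"
        tx = [SequenceRecord("t", "AAAA" + "".join(site) + "AAAA")]
        hits = scan_transcripts(mirna, tx)
        assert hits[0].expectation == 1.5

    def test_agrees_with_exhaustive_window_oracle(self):
        rng = np.random.default_rng(5)
        letters = np.array(list("ACGU"))
        mirna = SequenceRecord("m", "".join(letters[rng.integers(0, 4, 21)]))
        tx = SequenceRecord("t", "".join(letters[rng.integers(0, 4, 500)]))
        scheme = ScoreScheme(max_expectation=8.0)
        hits = scan_transcripts(mirna, [tx], scheme, max_expectation=8.0)
        got = {(h.site.start, h.expectation) for h in hits}
        L = len(mirna.sequence)
        expected = set()
        for start in range(len(tx.sequence) - L + 1):
            s = naive_window_score(mirna.sequence, tx.sequence[start : start + L])
            if s <= 8.0:
                expected.add((start, s))
        assert got == expected

    def test_scrambled_transcript_above_cap_gives_no_hits(self):
        mirna = SequenceRecord("m", "GGGGGGGGGGGGGGGGGGGG")
        tx = [SequenceRecord("t", "G" * 200)]  # G opposite G everywhere
        assert scan_transcripts(mirna, tx) == []

    def test_hits_sorted_by_expectation_then_position(self):
        mirna = SequenceRecord("m", "UGCCUGGCUCCCUGUAUGCC")
        perfect = revcomp(mirna.sequence)
        tx = [SequenceRecord("t", perfect + "AAAA" + perfect)]
        hits = scan_transcripts(mirna, tx)
        assert hits[0].expectation <= hits[-1].expectation
        starts = [h.site.start for h in hits if h.expectation == 0.0]
        assert starts == sorted(starts)


class TestUpe:
    def test_unstructured_context_opens_for_free(self):
        tx = "A" * 80
        assert upe_approx(tx, (30, 50)) == 0.0

    def test_blocking_one_arm_of_a_stem_costs_its_score(self):
        stem = "GGGGGGGG" + "AACAA" + "CCCCCCCC"
        tx = "A" * 20 + stem + "A" * 20
        # site covers the 5' arm of the stem entirely
        cost = upe_approx(tx, (20, 28), flank=30)
        assert cost == 24.0  # 8 G:C pairs at 3 apiece

    @given(st.integers(0, 5))
    @settings(max_examples=10)
    def test_nonnegative_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        tx = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 120)])
        assert upe_approx(tx, (50, 70)) >= 0.0

    def test_site_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            upe_approx("ACGU" * 10, (30, 50))
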