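"""Tag mapping, window extraction, star location and precursor calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canemir.fold import fold
from canemir.precursor import (
    call_precursor,
    dedup_candidates,
    extract_window,
    find_star,
    find_precursors,
    map_tag,
)
from canemir.records import GenomicInterval, SequenceRecord, revcomp


def naive_map(tag, genome):
    """Independent substring scan on both strands."""
    hits = []
    rc = revcomp(tag)
    for ref in genome:
        for i in range(len(ref.sequence) - len(tag) + 1):
            window = ref.sequence[i : i + len(tag)]
            if window == tag:
                hits.append((ref.id, i, "+"))
            if window == rc:
                hits.append((ref.id, i, "-"))
    return sorted(hits)


class TestMapTag:
    def test_absent_tag_gives_empty_list(self):
        genome = [SequenceRecord("chr1", "A" * 100)]
        assert map_tag("GGGGGGGGGGGGGGGGGGGG", genome) == []

    def test_planted_tag_found_at_planted_interval(self, tiny_genome):
        genome, hairpin, start = tiny_genome
        tag = hairpin[:21]
        hits = [h for h in map_tag(tag, genome) if h.strand == "+"]
        assert [(h.start, h.end) for h in hits] == [(start, start + 21)]

    def test_plus_hit_implies_mirrored_minus_hit_in_inverted_repeat(self, tiny_genome):
        genome, hairpin, start = tiny_genome
        tag = hairpin[:21]
        minus = [h for h in map_tag(tag, genome) if h.strand == "-"]
        # the star arm carries the reverse complement of the mature
        assert [(h.start, h.end) for h in minus] == [(start + 229, start + 250)]

    @given(st.text(alphabet="AC", min_size=4, max_size=8), st.integers(0, 3))
    @settings(max_examples=25)
    def test_agrees_with_naive_scan(self, tag, seed):
        rng = np.random.default_rng(seed)
        letters = np.array(list("ACGU"))
        genome = [SequenceRecord("g", "".join(letters[rng.integers(0, 4, 300)]))]
        got = sorted((h.ref_id, h.start, h.strand) for h in map_tag(tag, genome))
        assert got == naive_map(tag, genome)


class TestExtractWindow:
    GENOME = [SequenceRecord("chr1", "".join(
        np.array(list("ACGU"))[np.random.default_rng(0).integers(0, 4, 1000)]
    ))]

    def test_centered_window_has_mature_near_middle(self):
        hit = GenomicInterval("chr1", 500, 521)
        seq, mature, iv = extract_window(hit, self.GENOME)
        assert len(seq) == 250
        assert mature == (500 - iv.start, 521 - iv.start)
        assert abs(mature[0] - 115) <= 1

    def test_clipped_at_five_prime_end(self):
        hit = GenomicInterval("chr1", 10, 31)
        seq, mature, iv = extract_window(hit, self.GENOME)
        assert iv.start == 0
        assert mature[0] == 10

    def test_minus_strand_window_is_reverse_complement(self):
        hit_plus = GenomicInterval("chr1", 500, 521, "+")
        hit_minus = GenomicInterval("chr1", 500, 521, "-")
        seq_p, _, _ = extract_window(hit_plus, self.GENOME)
        seq_m, mature_m, _ = extract_window(hit_minus, self.GENOME)
        assert seq_m == revcomp(seq_p)
        assert mature_m[1] - mature_m[0] == 21

    def test_five_anchor_places_tag_at_window_start(self):
        hit = GenomicInterval("chr1", 500, 521)
        seq, mature, iv = extract_window(hit, self.GENOME, anchor="five")
        assert (iv.start, mature) == (500, (0, 21))


class TestFindStar:
    def test_perfect_duplex_has_zero_mismatches(self, tiny_genome):
        _, hairpin, _ = tiny_genome
        res = fold(hairpin)
        star, mm = find_star(res, (0, 21))
        assert mm == 0
        assert star is not None
        lo, hi = star
        assert lo >= 229 - 2 and hi <= 250

    def test_mature_spanning_loop_returns_none(self, tiny_genome):
        _, hairpin, _ = tiny_genome
        res = fold(hairpin)
        star, _ = find_star(res, (115, 136))
        assert star is None

    def test_engineered_unpaired_bases_counted_once_each(self):
        # 3 C:C oppositions inside a perfect stem
        rng = np.random.default_rng(11)
        letters = np.array(list("ACGU"))
        arm = list("".join(letters[rng.integers(0, 4, 40)]))
        for i in (5, 6, 7):
            arm[i] = "C"
        arm = "".join(arm)
        arm3 = list(revcomp(arm))
        n = 2 * len(arm) + 8
        for i in (5, 6, 7):
            arm3[(n - 1 - i) - (len(arm) + 8)] = "C"
        hairpin = arm + "AACAACAA" + "".join(arm3)
        res = fold(hairpin)
        star, mm = find_star(res, (0, 21))
        assert mm == 3


class TestCallPrecursor:
    def test_planted_hairpin_accepted(self, tiny_genome):
        genome, hairpin, start = tiny_genome
        hit = GenomicInterval("chr1", start, start + 21)
        cand = call_precursor(hairpin[:21], hit, genome)
        assert cand.accepted
        assert cand.duplex_mismatches == 0
        assert cand.fold.energy < 0

    def test_high_gc_window_fails_only_gc(self):
        rng = np.random.default_rng(2)
        letters = np.array(list("GC"))
        arm = "".join(letters[rng.integers(0, 2, 121)])
        hairpin = arm + "AACAACAA" + revcomp(arm)
        genome = [SequenceRecord("chr1", hairpin)]
        hit = GenomicInterval("chr1", 0, 21)
        cand = call_precursor(arm[:21], hit, genome)
        assert not cand.accepted
        assert [k for k, v in cand.verdicts.items() if not v] == ["gc_in_range"]

    def test_unstructured_window_fails_energy_sign(self):
        genome = [SequenceRecord("chr1", "A" * 300)]
        hit = GenomicInterval("chr1", 100, 121)
        cand = call_precursor("A" * 21, hit, genome)
        assert not cand.accepted
        assert cand.verdicts["mfe_negative"] is False

    def test_dedup_collapses_mirrored_candidates(self, tiny_genome):
        genome, hairpin, _ = tiny_genome
        tag = hairpin[:21]
        cands = [call_precursor(tag, h, genome) for h in map_tag(tag, genome)]
        assert len(cands) == 2  # plus hit + star-arm minus hit
        kept = dedup_candidates(cands)
        assert len(kept) == 1
        assert kept[0].accepted

    def test_find_precursors_end_to_end(self, tiny_genome):
        genome, hairpin, _ = tiny_genome
        cands = find_precursors([hairpin[:21]], genome)
        assert sum(c.accepted for c in cands) >= 1
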