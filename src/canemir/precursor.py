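"""Hairpin precursor discovery around mapped miRNA tags.

Each mapped tag nominates reference windows of a fixed size (250 nt by
default - the window the plant precursor-excision literature settled on),
which are folded and screened with four acceptance criteria: the window folds
into a single stem-loop hairpin, the mature tag lies entirely within one arm,
the mature has at most six mismatches with its star partner in the opposite
arm, the fold energy is strictly negative, and the window GC content lies in
[30, 70] %.  Because the exact excision register of a precursor around a
mapped read is not observable, three window placements are folded per hit
(centered on the tag, tag at the 5' end, tag at the 3' end) and the
best-scoring accepted placement is kept; when none is accepted the centered
window's verdicts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .fold import FoldResult, arms_of, fold, gc_content
from .records import GenomicInterval, SequenceRecord, revcomp

WINDOW = 250
MAX_STAR_MISMATCHES = 6
GC_RANGE = (30.0, 70.0)
STAR_OFFSET = 2  # conventional 2-nt 3' overhang of the star strand

CRITERIA = ("hairpin", "mature_in_arm", "star_mm_le6", "mfe_negative", "gc_in_range")


def map_tag(tag: str, genome: Sequence[SequenceRecord]) -> list[GenomicInterval]:
    """All exact ungapped occurrences of a tag on both strands.

    A minus-strand hit is an occurrence of the tag's reverse complement;
    coordinates are always on the plus strand, 0-based half-open.
    Overlapping occurrences are all reported.
    """
    hits = []
    rc = revcomp(tag)
    for ref in genome:
        for query, strand in ((tag, "+"), (rc, "-")):
            start = ref.sequence.find(query)
            while start != -1:
                hits.append(
                    GenomicInterval(ref.id, start, start + len(query), strand)
                )
                start = ref.sequence.find(query, start + 1)
    return hits


def extract_window(
    hit: GenomicInterval,
    genome: Sequence[SequenceRecord],
    window: int = WINDOW,
    anchor: str = "center",
) -> tuple[str, tuple[int, int], GenomicInterval]:
    """Extract the reference window around a mapped tag.

    Returns ``(window_seq, mature_span_in_window, window_interval)``.  The
    window sequence is in the tag's reading orientation (minus-strand hits are
    reverse complemented) and is clipped at reference ends.  ``anchor``
    places the tag at the window center, its 5' end, or its 3' end.
    """
    ref = next((r for r in genome if r.id == hit.ref_id), None)
    if ref is None:
        raise KeyError(f"reference {hit.ref_id!r} not in genome")
    L = len(ref.sequence)
    # genomic coordinates of the tag's 5' and 3' ends depend on strand
    if anchor == "center":
        mid = (hit.start + hit.end) // 2
        ws = mid - window // 2
    elif anchor == "five":
        ws = hit.start if hit.strand == "+" else hit.end - window
    elif anchor == "three":
        ws = hit.end - window if hit.strand == "+" else hit.start
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    we = min(L, ws + window)
    ws = max(0, ws)
    # clipping never drops the tag itself
    ws = min(ws, hit.start)
    we = max(we, hit.end)
    seq = ref.sequence[ws:we]
    if hit.strand == "+":
        mature = (hit.start - ws, hit.end - ws)
    else:
        seq = revcomp(seq)
        mature = (we - hit.end, we - hit.start)
    return seq, mature, GenomicInterval(hit.ref_id, ws, we, hit.strand)


def find_star(
    result: FoldResult, mature: tuple[int, int]
) -> tuple[tuple[int, int] | None, int]:
    """Locate the star partner of a mature span within a hairpin fold.

    Returns ``(star_span, duplex_mismatches)``.  The star span is the set of
    positions paired with the mature region, projected onto the opposite arm,
    extended to contiguity with the conventional 2-nt 3' offset;
    ``duplex_mismatches`` counts mature positions with no partner in the
    opposite arm (bulged or unpaired, once each).  ``(None, mismatches)`` when
    the structure is not a hairpin or the mature overlaps the loop.
    """
    arms = arms_of(result)
    s, e = mature
    if arms is None:
        return None, e - s
    five, loop, three = arms
    if s < loop[1] and e > loop[0]:  # mature overlaps the loop
        return None, e - s
    in_five = e <= loop[0]
    opposite = three if in_five else five
    partners = []
    mismatches = 0
    for i in range(s, e):
        p = result.pair_map[i]
        if p is not None and opposite[0] <= p < opposite[1]:
            partners.append(p)
        else:
            mismatches += 1
    if not partners:
        return None, mismatches
    lo, hi = min(partners), max(partners) + 1
    # the star's 3' end is its high-coordinate side; extend by the offset
    hi = min(hi + STAR_OFFSET, len(result.sequence))
    return (lo, hi), mismatches


@dataclass
class HairpinCandidate:
    """A folded reference window with per-criterion verdicts."""

    interval: GenomicInterval
    window_seq: str
    fold: FoldResult
    mature_tag: str
    mature_pos: tuple[int, int]
    star_pos: tuple[int, int] | None
    duplex_mismatches: int
    gc: float
    verdicts: dict[str, bool]
    accepted: bool

    def __post_init__(self) -> None:
        if set(self.verdicts) != set(CRITERIA):
            raise ValueError(f"verdicts must cover {CRITERIA}")
        if self.accepted != all(self.verdicts.values()):
            raise ValueError("accepted must equal the conjunction of verdicts")


def _evaluate_window(
    tag: str,
    window_seq: str,
    mature: tuple[int, int],
    interval: GenomicInterval,
    max_star_mm: int,
    gc_range: tuple[float, float],
) -> HairpinCandidate:
    result = fold(window_seq)
    gc = gc_content(window_seq)
    arms = arms_of(result)
    verdicts = {
        "hairpin": arms is not None,
        "mature_in_arm": True,
        "star_mm_le6": True,
        "mfe_negative": result.energy < 0,
        "gc_in_range": gc_range[0] <= gc <= gc_range[1],
    }
    star: tuple[int, int] | None = None
    mismatches = 0
    if arms is not None:
        five, loop, three = arms
        s, e = mature
        in_arm = (five[0] <= s and e <= five[1]) or (three[0] <= s and e <= three[1])
        verdicts["mature_in_arm"] = in_arm
        if in_arm:
            star, mismatches = find_star(result, mature)
            verdicts["star_mm_le6"] = mismatches <= max_star_mm
    return HairpinCandidate(
        interval=interval,
        window_seq=window_seq,
        fold=result,
        mature_tag=tag,
        mature_pos=mature,
        star_pos=star,
        duplex_mismatches=mismatches,
        gc=gc,
        verdicts=verdicts,
        accepted=all(verdicts.values()),
    )


def call_precursor(
    tag: str,
    hit: GenomicInterval,
    genome: Sequence[SequenceRecord],
    window: int = WINDOW,
    max_star_mm: int = MAX_STAR_MISMATCHES,
    gc_range: tuple[float, float] = GC_RANGE,
) -> HairpinCandidate:
    """Evaluate one mapped tag occurrence as a precursor candidate.

    The three window placements are folded; the accepted placement with the
    lowest fold energy wins.  When none is accepted, the placement that looks
    most like a precursor is reported (criteria compared in order: hairpin
    geometry, mature placement, duplex mismatches, energy sign, GC), so the
    failing verdicts describe the most hairpin-like window rather than an
    arbitrary one.
    """
    candidates = []
    for anchor in ("center", "five", "three"):
        seq, mature, iv = extract_window(hit, genome, window=window, anchor=anchor)
        candidates.append(
            _evaluate_window(tag, seq, mature, iv, max_star_mm, gc_range)
        )
    accepted = [c for c in candidates if c.accepted]
    if accepted:
        return min(accepted, key=lambda c: c.fold.energy)
    return max(candidates, key=lambda c: tuple(c.verdicts[k] for k in CRITERIA))


def dedup_candidates(
    candidates: Sequence[HairpinCandidate], min_overlap: float = 0.8
) -> list[HairpinCandidate]:
    """Collapse candidates whose windows overlap >= ``min_overlap``.

    Accepted candidates are preferred, then lower fold energy.  Strand is
    ignored: a hairpin and its reverse complement describe the same locus.
    """
    ranked = sorted(
        candidates, key=lambda c: (not c.accepted, c.fold.energy, c.interval.start)
    )
    kept: list[HairpinCandidate] = []
    for cand in ranked:
        if any(cand.interval.overlap_fraction(k.interval) >= min_overlap for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: (c.interval.ref_id, c.interval.start))
    return kept


def find_precursors(
    tags: Sequence[str],
    genome: Sequence[SequenceRecord],
    window: int = WINDOW,
    max_star_mm: int = MAX_STAR_MISMATCHES,
    gc_range: tuple[float, float] = GC_RANGE,
) -> list[HairpinCandidate]:
    """Map every tag and call candidates, deduplicated by window overlap."""
    out = []
    for tag in tags:
        cands = [
            call_precursor(tag, hit, genome, window, max_star_mm, gc_range)
            for hit in map_tag(tag, genome)
        ]
        out.extend(dedup_candidates(cands))
    return out
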