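"""Tag annotation: known-mature matching and category assignment.

Tags are compared to a mature miRNA reference set by ungapped alignment with
at most two mismatches (the conventional cross-species matching rule) and a
configurable end-shift tolerance that accommodates isomiR-like 5'/3' length
variants.  Structural RNA classes (rRNA, tRNA, sn/snoRNA) are assigned by
exact substring match against user-supplied per-class references; 24-nt tags
that map to the genome but hit no reference class are labelled siRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .preprocess import CATEGORY_PRECEDENCE
from .records import SequenceRecord


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length sequences; N always mismatches."""
    if len(a) != len(b):
        raise ValueError(f"hamming distance needs equal lengths ({len(a)} vs {len(b)})")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


@dataclass(frozen=True)
class MatureMatch:
    """An ungapped tag-to-mature alignment within the mismatch budget."""

    tag: str
    reference_id: str
    mismatches: int
    offset: int  # tag start within the reference mature (may be negative)


def _count_mismatches(tag: str, ref: str, offset: int) -> int:
    """Mismatches of ``tag`` aligned so tag[i] faces ref[i + offset].

    Positions falling outside the reference (overhangs) count as mismatches;
    N never matches anything.
    """
    mm = 0
    for i, base in enumerate(tag):
        j = i + offset
        if 0 <= j < len(ref):
            if base != ref[j] or base == "N":
                mm += 1
        else:
            mm += 1
    return mm


def match_mature(
    tag: str,
    mature_refs: Sequence[SequenceRecord],
    max_mm: int = 2,
    shift: int = 2,
) -> MatureMatch | None:
    """Best ungapped match of a tag against a mature reference set.

    Offsets in ``[-shift, +shift]`` are examined; ties break by fewer
    mismatches, then smaller ``|offset|``, then lexicographic reference id.
    Returns ``None`` when every alignment exceeds ``max_mm`` mismatches.
    ``shift=0`` gives the strict fixed-register mode.
    """
    if not mature_refs:
        raise ValueError("mature reference set is empty")
    best: MatureMatch | None = None
    for ref in mature_refs:
        for offset in range(-shift, shift + 1):
            mm = _count_mismatches(tag, ref.sequence, offset)
            if mm > max_mm:
                continue
            cand = MatureMatch(tag, ref.id, mm, offset)
            if best is None or (cand.mismatches, abs(cand.offset), cand.reference_id) < (
                best.mismatches, abs(best.offset), best.reference_id
            ):
                best = cand
    return best


def classify_tag(
    tag: str,
    mature_refs: Sequence[SequenceRecord] = (),
    class_refs: Mapping[str, Sequence[SequenceRecord]] | None = None,
    genome: Sequence[SequenceRecord] | None = None,
    max_mm: int = 2,
    shift: int = 2,
    precedence: Sequence[str] = CATEGORY_PRECEDENCE,
) -> str:
    """Assign one category to a tag under a fixed class precedence.

    miRNA requires a mature match; structural classes require the tag as an
    exact substring of a class reference; siRNA requires a 24-nt tag with a
    genome hit and no other class; everything else is Unannotated.  Total and
    deterministic under fixed precedence.
    """
    class_refs = class_refs or {}

    def hits(category: str) -> bool:
        if category == "miRNA":
            return bool(mature_refs) and match_mature(tag, mature_refs, max_mm, shift) is not None
        if category == "siRNA":
            if len(tag) != 24 or genome is None:
                return False
            from .precursor import map_tag

            return bool(map_tag(tag, genome))
        if category == "Unannotated":
            return True
        return any(tag in ref.sequence for ref in class_refs.get(category, ()))

    for category in precedence:
        if hits(category):
            return category
    return "Unannotated"


def annotate_table(
    tags: Sequence[str],
    mature_refs: Sequence[SequenceRecord] = (),
    class_refs: Mapping[str, Sequence[SequenceRecord]] | None = None,
    genome: Sequence[SequenceRecord] | None = None,
    max_mm: int = 2,
    shift: int = 2,
) -> dict[str, str]:
    """Category per tag, suitable for :func:`canemir.preprocess.category_summary`."""
    return {
        tag: classify_tag(tag, mature_refs, class_refs, genome, max_mm, shift)
        for tag in tags
    }
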