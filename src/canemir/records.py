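"""Shared sequence and coordinate primitives.

All sequences are held internally in the RNA alphabet ``{A, C, G, U, N}``;
DNA input is converted (``T`` -> ``U``) on ingestion and reverse complements
are defined with ``A <-> U``.  ``N`` never pairs and always counts as a
mismatch wherever mismatches are counted.

Coordinates are 0-based half-open internally; every serialized or reported
coordinate is 1-based inclusive, the convention used throughout the plant
sRNA literature for target-site start/end positions.
"""

from __future__ import annotations

from dataclasses import dataclass

RNA_ALPHABET = frozenset("ACGUN")

# lowercase/uppercase DNA or RNA -> canonical uppercase RNA
_NORMALIZE = str.maketrans("acgtunACGTUN", "ACGUUNACGUUN")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class ParseError(ValueError):
    """Raised when an input file violates its format."""


def as_rna(raw: str) -> str:
    """Normalize a raw sequence string to uppercase RNA.

    ``T``/``t`` become ``U``; lowercase is uppercased; any character outside
    the RNA alphabet (after normalization) raises :class:`ValueError`.
    """
    seq = raw.strip().translate(_NORMALIZE)
    if not set(seq) <= RNA_ALPHABET:
        bad = sorted(set(seq) - RNA_ALPHABET)
        raise ValueError(f"sequence contains non-RNA characters: {bad!r}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet (A<->U, G<->C, N->N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence in canonical RNA form."""

    id: str
    sequence: str
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not set(self.sequence) <= RNA_ALPHABET:
            raise ValueError(
                f"record {self.id!r}: sequence not in canonical RNA form; "
                "use SequenceRecord.from_raw"
            )

    @classmethod
    def from_raw(cls, id: str, raw: str, description: str | None = None) -> "SequenceRecord":
        return cls(id=id, sequence=as_rna(raw), description=description)

    def __len__(self) -> int:
        return len(self.sequence)


_CONDITIONS = ("irrigated", "drought")


@dataclass
class LibraryMeta:
    """Metadata for one sequencing library (a cultivar x condition pool)."""

    name: str
    cultivar: str = ""
    condition: str = ""
    total_clean_reads: int = 0

    def __post_init__(self) -> None:
        if self.condition and self.condition not in _CONDITIONS:
            raise ValueError(
                f"library {self.name!r}: condition must be one of {_CONDITIONS}"
            )
        if self.total_clean_reads < 0:
            raise ValueError(f"library {self.name!r}: negative total_clean_reads")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a reference sequence.

    ``start1``/``end1`` give the 1-based inclusive coordinates used in all
    user-facing output.
    """

    ref_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.ref_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def start1(self) -> int:
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.end

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_fraction(self, other: "GenomicInterval") -> float:
        """Overlap length divided by the shorter interval's length (0 if on
        different references)."""
        if self.ref_id != other.ref_id:
            return 0.0
        ov = min(self.end, other.end) - max(self.start, other.start)
        if ov <= 0:
            return 0.0
        return ov / min(len(self), len(other))
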