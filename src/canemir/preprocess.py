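"""Adaptor removal, length filtering, tag collapsing and library summaries.

The preprocessing contract mirrors standard sRNA-seq practice: the 3' adaptor
is located by exact prefix match (configurable minimum overlap, optionally one
mismatch), everything from the adaptor onwards is removed, inserts outside the
19-24 nt range are discarded, and surviving reads are collapsed to unique tags
with one count column per library.  The gel-selection range used at the bench
is wider than the computational filter and plays no role here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .records import LibraryMeta, SequenceRecord

#: documented default 3' adaptor used by the synthetic generator
DEFAULT_ADAPTOR = "UCGUAUGCCGUCUUCUGCUUG"

MIN_TAG_LEN = 19
MAX_TAG_LEN = 24

CATEGORIES = ("miRNA", "rRNA", "siRNA", "snRNA", "snoRNA", "tRNA", "Unannotated")

#: precedence when a tag matches several reference classes
CATEGORY_PRECEDENCE = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "siRNA", "Unannotated")

TRIMMED = "trimmed"
NO_ADAPTOR = "no_adaptor"
NO_INSERT = "no_insert"


class TrimResult(NamedTuple):
    insert: str
    status: str  # TRIMMED / NO_ADAPTOR / NO_INSERT


def trim_adaptor(
    read: str | SequenceRecord,
    adaptor: str,
    min_overlap: int = 6,
    max_mismatch: int = 0,
) -> TrimResult:
    """Remove the leftmost 3' adaptor occurrence from a read.

    The adaptor's prefix (length >= ``min_overlap``, at most ``max_mismatch``
    mismatches) is searched left to right; the match and everything 3' of it
    are removed.  A read with no detectable adaptor is returned whole and
    flagged ``no_adaptor`` (it may be a full-length insert); a read whose
    insert would be empty returns the ``no_insert`` sentinel.  Total function:
    never raises on sequence content.
    """
    seq = read.sequence if isinstance(read, SequenceRecord) else read
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n = len(seq)
    pos = None
    if max_mismatch == 0:
        core = adaptor[: min(min_overlap, len(adaptor))]
        start = seq.find(core)
        while start != -1:
            span = min(len(adaptor), n - start)
            if span >= min_overlap and seq[start : start + span] == adaptor[:span]:
                pos = start
                break
            start = seq.find(core, start + 1)
    else:
        for start in range(0, n - min_overlap + 1):
            span = min(len(adaptor), n - start)
            if span < min_overlap:
                break
            mm = sum(1 for a, b in zip(seq[start : start + span], adaptor) if a != b)
            if mm <= max_mismatch:
                pos = start
                break
    if pos is None:
        return TrimResult(seq, NO_ADAPTOR)
    if pos == 0:
        return TrimResult("", NO_INSERT)
    return TrimResult(seq[:pos], TRIMMED)


def filter_length(tag: str, min_len: int = MIN_TAG_LEN, max_len: int = MAX_TAG_LEN) -> bool:
    """Keep a tag iff ``min_len <= len(tag) <= max_len``."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return min_len <= len(tag) <= max_len


@dataclass
class PreprocessStats:
    raw_reads: int = 0
    trimmed: int = 0
    no_adaptor: int = 0
    no_insert: int = 0
    length_discarded: int = 0
    clean_reads: int = 0


def preprocess_reads(
    reads: Iterable[str],
    adaptor: str = DEFAULT_ADAPTOR,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    min_overlap: int = 6,
    max_mismatch: int = 0,
    discard_untrimmed: bool = False,
) -> tuple[Counter, PreprocessStats]:
    """Trim + length-filter one library, returning clean-tag counts.

    Identical raw reads are deduplicated before trimming (trimming is a pure
    per-sequence function, so this changes nothing but speed).
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    raw = Counter(reads)
    clean: Counter = Counter()
    stats = PreprocessStats()
    for seq, count in raw.items():
        stats.raw_reads += count
        res = trim_adaptor(seq, adaptor, min_overlap=min_overlap, max_mismatch=max_mismatch)
        if res.status == NO_INSERT:
            stats.no_insert += count
            continue
        if res.status == NO_ADAPTOR:
            stats.no_adaptor += count
            if discard_untrimmed:
                continue
        else:
            stats.trimmed += count
        if not filter_length(res.insert, min_len, max_len):
            stats.length_discarded += count
            continue
        clean[res.insert] += count
        stats.clean_reads += count
    return clean, stats


class TagTable:
    """Unique tag sequences with one count column per library.

    The central ledger of the pipeline: rows are unique tags, columns are
    libraries, and per-library column sums define the library totals used by
    every normalization downstream.
    """

    def __init__(self, counts: pd.DataFrame, libraries: list[LibraryMeta]):
        if list(counts.columns) != [lib.name for lib in libraries]:
            raise ValueError("count columns must match library names, in order")
        if len({lib.name for lib in libraries}) != len(libraries):
            raise ValueError("library names must be unique")
        if (counts.values < 0).any():
            raise ValueError("tag counts must be non-negative")
        self.counts = counts.astype(int)
        self.libraries = libraries
        for lib in self.libraries:
            lib.total_clean_reads = int(self.counts[lib.name].sum())

    @property
    def library_names(self) -> list[str]:
        return [lib.name for lib in self.libraries]

    @property
    def totals(self) -> dict[str, int]:
        return {lib.name: lib.total_clean_reads for lib in self.libraries}

    def library(self, name: str) -> LibraryMeta:
        for lib in self.libraries:
            if lib.name == name:
                return lib
        raise KeyError(f"unknown library {name!r}")

    def __len__(self) -> int:
        return len(self.counts)

    def equals(self, other: "TagTable") -> bool:
        return (
            self.library_names == other.library_names
            and self.counts.sort_index().equals(other.counts.sort_index())
        )


def collapse_tags(
    reads_per_library: Mapping[str, Iterable[str] | Counter],
    libraries: list[LibraryMeta] | None = None,
) -> TagTable:
    """Collapse clean reads (or pre-counted tags) into a :class:`TagTable`."""
    if libraries is None:
        libraries = [LibraryMeta(name=name) for name in reads_per_library]
    counters = {}
    for lib in libraries:
        reads = reads_per_library.get(lib.name, ())
        counters[lib.name] = reads if isinstance(reads, Counter) else Counter(reads)
    tags = sorted(set().union(*[c.keys() for c in counters.values()]) if counters else ())
    data = {
        lib.name: [counters[lib.name].get(t, 0) for t in tags] for lib in libraries
    }
    df = pd.DataFrame(data, index=pd.Index(tags, name="tag"), dtype=int)
    return TagTable(df, libraries)


def length_histogram(
    table: TagTable,
    library: str,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> dict[int, int]:
    """Total read counts per tag length over ``[min_len, max_len]``."""
    table.library(library)  # raises on unknown library
    hist = {length: 0 for length in range(min_len, max_len + 1)}
    if len(table):
        lengths = table.counts.index.str.len()
        counts = table.counts[library].to_numpy()
        for length, count in zip(lengths, counts):
            hist[int(length)] += int(count)
    return hist


@dataclass
class CategorySummary:
    """Per-category accounting of one library's unique tags and total reads.

    ``unique``/``total`` map category name -> count; percentages are relative
    to the library's grand totals, so category totals partition the library
    total exactly and percentages sum to 100 within rounding.
    """

    unique: dict[str, int] = field(default_factory=dict)
    total: dict[str, int] = field(default_factory=dict)

    @property
    def grand_unique(self) -> int:
        return sum(self.unique.values())

    @property
    def grand_total(self) -> int:
        return sum(self.total.values())

    def unique_percent(self, category: str) -> float:
        return 100.0 * self.unique.get(category, 0) / self.grand_unique

    def total_percent(self, category: str) -> float:
        return 100.0 * self.total.get(category, 0) / self.grand_total

    def to_frame(self) -> pd.DataFrame:
        cats = [c for c in CATEGORIES if c in self.unique or c in self.total]
        return pd.DataFrame(
            {
                "unique": [self.unique.get(c, 0) for c in cats],
                "unique_pct": [round(self.unique_percent(c), 2) for c in cats],
                "total": [self.total.get(c, 0) for c in cats],
                "total_pct": [round(self.total_percent(c), 2) for c in cats],
            },
            index=pd.Index(cats, name="category"),
        )


def category_summary(
    table: TagTable, annotations: Mapping[str, str]
) -> dict[str, CategorySummary]:
    """Tally unique tags and total reads per category for every library.

    Every tag must carry exactly one category (``Unannotated`` counts as a
    category); a missing annotation is an error.
    """
    for tag in table.counts.index:
        cat = annotations.get(tag)
        if cat is None:
            raise ValueError(f"tag {tag!r} has no category annotation")
        if cat not in CATEGORIES:
            raise ValueError(f"tag {tag!r}: unknown category {cat!r}")
    out = {}
    cats = pd.Index([annotations[t] for t in table.counts.index], name="category")
    for lib in table.libraries:
        col = table.counts[lib.name]
        summary = CategorySummary()
        grouped_total = col.groupby(cats).sum()
        grouped_unique = (col > 0).groupby(cats).sum()
        for cat in CATEGORIES:
            if cat in grouped_total.index:
                summary.total[cat] = int(grouped_total[cat])
                summary.unique[cat] = int(grouped_unique[cat])
        out[lib.name] = summary
    return out
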