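"""Readers and writers for the external formats the pipeline touches.

FASTA and FASTQ parsing is delegated to Biopython's low-level iterators and
wrapped so that every sequence enters the package in canonical RNA form
(uppercase, T converted to U).  Qualities are parsed but not used: sRNA
libraries are single-end and length-selected, and no quality trimming is done.

Tag tables are plain TSV (one row per unique tag, one count column per
library) with library metadata preserved in ``#library`` header comments so
that write -> read is the identity.  Precursor calls are emitted as GFF3 with
1-based inclusive coordinates.
"""

from __future__ import annotations

import typing
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .records import GenomicInterval, LibraryMeta, ParseError, SequenceRecord, as_rna

if typing.TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .precursor import HairpinCandidate
    from .preprocess import TagTable


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of normalized :class:`SequenceRecord`.

    Order is preserved; ``T`` becomes ``U``; ``N`` is allowed.  An empty
    sequence body or a file whose first non-blank line is not a header is a
    :class:`ParseError`.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()[:40]!r}"
                    )
                break
        else:
            return []
        handle.seek(0)
        records = []
        for idx, (title, seq) in enumerate(SimpleFastaParser(handle), start=1):
            name, _, desc = title.partition(" ")
            if not seq:
                raise ParseError(f"{path}: record {idx} ({name!r}): empty sequence")
            try:
                records.append(SequenceRecord.from_raw(name, seq, desc or None))
            except ValueError as exc:
                raise ParseError(f"{path}: record {idx} ({name!r}): {exc}") from exc
    return records


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream a 4-line FASTQ file as normalized :class:`SequenceRecord`.

    Qualities are validated by the underlying parser and discarded.
    Truncated records raise :class:`ParseError` naming the record index.
    """
    path = Path(path)
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        idx = 0
        while True:
            try:
                title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(f"{path}: after record {idx}: {exc}") from exc
            idx += 1
            name = title.split(None, 1)[0]
            try:
                yield SequenceRecord.from_raw(name, seq)
            except ValueError as exc:
                raise ParseError(f"{path}: record {idx} ({name!r}): {exc}") from exc


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            handle.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    """Write ``(name, sequence)`` pairs as FASTQ with a placeholder quality."""
    with open(path, "w") as handle:
        for name, seq in reads:
            handle.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# tag tables


def write_tag_table(table: "TagTable", path: str | Path) -> None:
    """Serialize a tag table as TSV: ``#library`` metadata comments, then a
    header line ``tag<TAB>lib1<TAB>...`` and one row per unique tag."""
    with open(path, "w") as handle:
        for lib in table.libraries:
            handle.write(
                f"#library\t{lib.name}\t{lib.cultivar}\t{lib.condition}\t{lib.total_clean_reads}\n"
            )
        handle.write("tag\t" + "\t".join(lib.name for lib in table.libraries) + "\n")
        df = table.counts
        for tag, row in df.iterrows():
            handle.write(str(tag) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_tag_table(path: str | Path) -> "TagTable":
    """Inverse of :func:`write_tag_table`.

    Duplicate tag rows or negative counts are a :class:`ParseError`.
    """
    from .preprocess import TagTable

    path = Path(path)
    metas: list[LibraryMeta] = []
    with open(path) as handle:
        pos = handle.tell()
        line = handle.readline()
        while line.startswith("#library\t"):
            _, name, cultivar, condition, total = line.rstrip("\n").split("\t")
            metas.append(
                LibraryMeta(
                    name=name, cultivar=cultivar, condition=condition,
                    total_clean_reads=int(total),
                )
            )
            pos = handle.tell()
            line = handle.readline()
        handle.seek(pos)
        df = pd.read_csv(handle, sep="\t", dtype={"tag": str})
    if "tag" not in df.columns:
        raise ParseError(f"{path}: missing 'tag' column")
    if df["tag"].duplicated().any():
        dup = df["tag"][df["tag"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate tag row {dup!r}")
    df = df.set_index("tag")
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative count")
    if not metas:
        metas = [LibraryMeta(name=c) for c in df.columns]
    if [m.name for m in metas] != list(df.columns):
        raise ParseError(f"{path}: #library metadata does not match count columns")
    return TagTable(df.astype(int), metas)


# ---------------------------------------------------------------------------
# GFF3

_GFF_SOURCE = "canemir"


def write_gff3(
    candidates: "Iterable[HairpinCandidate]",
    path: str | Path,
    ref_lengths: dict[str, int] | None = None,
) -> None:
    """Write precursor candidates as GFF3 (1-based inclusive coordinates).

    Attributes carry the fold energy, GC percentage, per-criterion verdicts
    and the overall accepted flag.  With ``ref_lengths`` given, an interval
    beyond its reference end raises :class:`ValueError`.
    """
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for i, cand in enumerate(candidates, start=1):
            iv = cand.interval
            if ref_lengths is not None:
                length = ref_lengths.get(iv.ref_id)
                if length is None or iv.end > length:
                    raise ValueError(
                        f"interval {iv} outside reference (length {length})"
                    )
            verdicts = ",".join(k for k, v in cand.verdicts.items() if not v) or "none"
            attrs = (
                f"ID=hairpin{i};mature={cand.mature_tag};"
                f"mfe={cand.fold.energy:g};gc={cand.gc:.2f};"
                f"failed={verdicts};accepted={str(cand.accepted).lower()}"
            )
            handle.write(
                "\t".join(
                    [
                        iv.ref_id,
                        _GFF_SOURCE,
                        "miRNA_primary_transcript",
                        str(iv.start1),
                        str(iv.end1),
                        ".",
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_config(path: str | Path) -> dict:
    """Load a YAML run configuration as a plain dict."""
    import yaml

    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: run configuration must be a mapping")
    return data
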