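"""End-to-end orchestration: preprocess -> annotate -> precursors -> DE -> targets.

A run is a pure function of (inputs, configuration, seed): the report bundle
contains a category summary, per-library length histograms, a differential
expression table, a target table, a GFF3 of precursor calls and a log of the
parameters used.  Re-running with the same configuration reproduces every
table byte for byte.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .annotate import annotate_table
from .diffexpr import de_table
from .io import read_fasta, read_fastq, write_gff3, write_tag_table
from .precursor import find_precursors
from .preprocess import (
    DEFAULT_ADAPTOR,
    MAX_TAG_LEN,
    MIN_TAG_LEN,
    category_summary,
    collapse_tags,
    length_histogram,
    preprocess_reads,
)
from .records import LibraryMeta
from .targets import DEFAULT_SCHEME, ScoreScheme, hits_to_frame, scan_transcripts

_KNOWN_KEYS = {
    "libraries", "genome", "mature_ref", "class_refs", "transcripts", "outdir",
    "adaptor", "min_len", "max_len", "min_overlap", "contrasts", "alpha",
    "fc_threshold", "max_expectation", "seed", "window", "max_star_mm",
    "gc_min", "gc_max",
}


@dataclass
class RunConfig:
    """Validated run configuration (typically loaded from YAML)."""

    libraries: dict[str, dict]  # name -> {fastq, cultivar, condition}
    genome: str | None = None
    mature_ref: str | None = None
    class_refs: dict[str, str] = field(default_factory=dict)
    transcripts: str | None = None
    outdir: str = "canemir_out"
    adaptor: str = DEFAULT_ADAPTOR
    min_len: int = MIN_TAG_LEN
    max_len: int = MAX_TAG_LEN
    min_overlap: int = 6
    contrasts: dict[str, list[str]] = field(default_factory=dict)
    alpha: float = 0.05
    fc_threshold: float = 2.0
    max_expectation: float = DEFAULT_SCHEME.max_expectation
    seed: int = 0
    window: int = 250
    max_star_mm: int = 6
    gc_min: float = 30.0
    gc_max: float = 70.0

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "libraries" not in data or not data["libraries"]:
            raise ValueError("configuration must define at least one library")
        cfg = cls(**data)
        if cfg.min_len > cfg.max_len:
            raise ValueError("min_len > max_len")
        for label, pair in cfg.contrasts.items():
            if len(pair) != 2 or any(name not in cfg.libraries for name in pair):
                raise ValueError(f"contrast {label!r} must name two configured libraries")
        for name, spec in cfg.libraries.items():
            if "fastq" not in spec:
                raise ValueError(f"library {name!r}: missing 'fastq' path")
        return cfg


def run_pipeline(config: RunConfig, log=sys.stderr) -> dict[str, Path]:
    """Execute all stages and write the report bundle into ``config.outdir``.

    Returns a mapping of artifact name -> path.  Any stage failure aborts
    with the stage name in the exception message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines = [f"canemir {__version__}", f"seed {config.seed}"]

    def stage(name):
        log_lines.append(f"stage: {name}")
        print(f"[canemir] {name}", file=log)

    try:
        stage("preprocess")
        metas, counters = [], {}
        for name, spec in config.libraries.items():
            meta = LibraryMeta(name, spec.get("cultivar", ""), spec.get("condition", ""))
            reads = (rec.sequence for rec in read_fastq(spec["fastq"]))
            counters[name], stats = preprocess_reads(
                reads,
                adaptor=config.adaptor,
                min_len=config.min_len,
                max_len=config.max_len,
                min_overlap=config.min_overlap,
            )
            metas.append(meta)
            log_lines.append(
                f"  {name}: raw={stats.raw_reads} trimmed={stats.trimmed} "
                f"no_adaptor={stats.no_adaptor} no_insert={stats.no_insert} "
                f"len_discarded={stats.length_discarded} clean={stats.clean_reads}"
            )
        table = collapse_tags(counters, metas)
        artifacts["tag_table"] = outdir / "tag_table.tsv"
        write_tag_table(table, artifacts["tag_table"])

        hist_rows = []
        for meta in metas:
            hist = length_histogram(table, meta.name, config.min_len, config.max_len)
            for length, count in hist.items():
                hist_rows.append({"library": meta.name, "length": length, "reads": count})
        artifacts["length_histograms"] = outdir / "length_histograms.tsv"
        pd.DataFrame(hist_rows).to_csv(artifacts["length_histograms"], sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    genome = read_fasta(config.genome) if config.genome else None
    mature_refs = read_fasta(config.mature_ref) if config.mature_ref else []
    class_refs = {cls: read_fasta(path) for cls, path in config.class_refs.items()}

    try:
        stage("annotate")
        annotations = annotate_table(
            list(table.counts.index), mature_refs, class_refs, genome
        )
        summaries = category_summary(table, annotations)
        frames = []
        for name, summary in summaries.items():
            frame = summary.to_frame().reset_index()
            frame.insert(0, "library", name)
            frames.append(frame)
        artifacts["category_summary"] = outdir / "category_summary.tsv"
        pd.concat(frames).to_csv(artifacts["category_summary"], sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'annotate' failed: {exc}") from exc

    mirna_tags = [t for t, cat in annotations.items() if cat == "miRNA"]

    try:
        stage("precursors")
        candidates = []
        if genome is not None:
            candidates = find_precursors(
                mirna_tags,
                genome,
                window=config.window,
                max_star_mm=config.max_star_mm,
                gc_range=(config.gc_min, config.gc_max),
            )
        artifacts["precursors"] = outdir / "precursors.gff3"
        write_gff3(candidates, artifacts["precursors"])
        log_lines.append(
            f"  candidates={len(candidates)} accepted={sum(c.accepted for c in candidates)}"
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'precursors' failed: {exc}") from exc

    try:
        stage("diffexpr")
        contrasts = {k: tuple(v) for k, v in config.contrasts.items()}
        de = de_table(
            table, contrasts, features=mirna_tags,
            alpha=config.alpha, fc_threshold=config.fc_threshold,
        ) if contrasts else pd.DataFrame()
        artifacts["de_table"] = outdir / "de_table.tsv"
        de.to_csv(artifacts["de_table"], sep="\t", index=False, float_format="%.6g")
    except Exception as exc:
        raise RuntimeError(f"stage 'diffexpr' failed: {exc}") from exc

    try:
        stage("targets")
        rows = []
        if config.transcripts and mature_refs:
            transcripts = read_fasta(config.transcripts)
            scheme = ScoreScheme(max_expectation=config.max_expectation)
            for ref in mature_refs:
                hits = scan_transcripts(ref, transcripts, scheme, compute_upe=True)
                rows.append(hits_to_frame(hits))
        artifacts["targets"] = outdir / "targets.tsv"
        frame = pd.concat(rows) if rows else hits_to_frame([])
        frame.to_csv(artifacts["targets"], sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'targets' failed: {exc}") from exc

    artifacts["log"] = outdir / "run_log.txt"
    artifacts["log"].write_text("\n".join(log_lines) + "\n")
    return artifacts
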