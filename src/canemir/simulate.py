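"""Synthetic reference genomes and sRNA libraries with planted ground truth.

The generator emulates the study design every pipeline stage is tested
against: a background genome carrying planted miRNA hairpin loci (perfect
inverted repeats with the mature in one arm and a star partner offset 2 nt at
the 3' ends), and two-cultivar x two-condition read libraries with known
per-locus abundances and drought fold changes, a bimodal 21/24-nt background
(siRNA-like 24-mers plus uniform 19-24 nt degradation tags), and a fixed 3'
adaptor appended to every read.

Designated violation loci break exactly one precursor criterion each:

``gc``         GC-rich arms push the window outside the 30-70 % band;
``loop``       the mature tag spans the hairpin loop;
``mismatch``   seven mature positions face non-pairing bases (> 6 allowed);
``structure``  two disjoint stems, so no single stem-loop exists.

Every planted locus is verified against the precursor caller at construction
time and redrawn (same seeded stream, bounded retries) in the rare event a
traceback tie breaks the intended verdict pattern, so the truth manifest is
guaranteed, not merely probable.  Generation is byte-deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .diffexpr import call_de
from .precursor import call_precursor, map_tag
from .preprocess import DEFAULT_ADAPTOR, collapse_tags, preprocess_reads
from .records import GenomicInterval, LibraryMeta, SequenceRecord, revcomp

HAIRPIN_LEN = 250
LOOP_SEQ = "AACAACAA"  # A/C only: cannot pair internally, no G for stray G:C
ARM_LEN = (HAIRPIN_LEN - len(LOOP_SEQ)) // 2
MATURE_LEN = 21
VIOLATION_KINDS = ("gc", "loop", "mismatch", "structure")

_RNA = np.array(list("ACGU"))
_RNA2DNA = str.maketrans("ACGU", "ACGT")
_DNA2RNA = str.maketrans("ACGT", "ACGU")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_RNA[rng.choice(4, size=n, p=p)])


@dataclass
class PlantedLocus:
    """One planted hairpin (or designated violator) and its ground truth."""

    locus_id: str
    kind: str  # "conforming" or one of VIOLATION_KINDS
    interval: GenomicInterval  # full planted construct
    mature_interval: GenomicInterval
    mature: str
    star: str
    conforms: dict[str, bool]
    abundance: float  # expected clean-read count at the reference depth
    fold_change: float  # drought / irrigated


@dataclass
class TruthManifest:
    """Everything needed to score pipeline output against the simulation."""

    seed: int
    genome_len: int
    gc_background: float
    reference_depth: int
    adaptor: str
    loci: list[PlantedLocus] = field(default_factory=list)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "genome_len": self.genome_len,
            "gc_background": self.gc_background,
            "reference_depth": self.reference_depth,
            "adaptor": self.adaptor,
            "loci": [
                {
                    **asdict(locus),
                    "interval": asdict(locus.interval),
                    "mature_interval": asdict(locus.mature_interval),
                }
                for locus in self.loci
            ],
        }
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthManifest":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        loci = [
            PlantedLocus(
                **{
                    **entry,
                    "interval": GenomicInterval(**entry["interval"]),
                    "mature_interval": GenomicInterval(**entry["mature_interval"]),
                }
            )
            for entry in data.pop("loci")
        ]
        return cls(loci=loci, **data)


# ---------------------------------------------------------------------------
# locus construction


def _build_conforming(rng, gc: float = 0.5) -> tuple[str, int, dict]:
    arm5 = _random_seq(rng, ARM_LEN, gc)
    hairpin = arm5 + LOOP_SEQ + revcomp(arm5)
    return hairpin, 0, {"expected_fail": set()}


def _build_gc(rng) -> tuple[str, int, dict]:
    hairpin, off, _ = _build_conforming(rng, gc=0.85)
    return hairpin, off, {"expected_fail": {"gc_in_range"}}


def _build_loop(rng) -> tuple[str, int, dict]:
    """Mature centered on the loop so its midpoint is the hairpin midpoint."""
    arm5 = _random_seq(rng, ARM_LEN, 0.5)
    hairpin = arm5 + LOOP_SEQ + revcomp(arm5)
    # centered so the tag's midpoint is the hairpin midpoint: mature [115, 136)
    offset = HAIRPIN_LEN // 2 - MATURE_LEN // 2
    return hairpin, offset, {"expected_fail": {"mature_in_arm"}}


def _build_mismatch(rng, n_bulge: int = 7) -> tuple[str, int, dict]:
    """Seven C:C oppositions in the mature region of an otherwise perfect stem."""
    arm5 = list(_random_seq(rng, ARM_LEN, 0.5))
    bulge = range(7, 7 + n_bulge)
    for i in bulge:
        arm5[i] = "C"
    arm5 = "".join(arm5)
    arm3 = list(revcomp(arm5))
    for i in bulge:
        # partner of hairpin position i sits at HAIRPIN_LEN-1-i; local arm3 index:
        arm3[(HAIRPIN_LEN - 1 - i) - (ARM_LEN + len(LOOP_SEQ))] = "C"
    hairpin = arm5 + LOOP_SEQ + "".join(arm3)
    return hairpin, 0, {"expected_fail": {"star_mm_le6"}}


def _build_structure(rng) -> tuple[str, int, dict]:
    """Two disjoint stems from non-interacting alphabets; no single hairpin."""
    gc_arm = _random_seq(rng, 25, 1.0)  # G/C only (mature = first 21)
    au_arm = "".join(_RNA[[0, 3]][rng.integers(0, 2, size=25)])  # A/U only
    construct = (
        gc_arm + "AAAAA" + revcomp(gc_arm)
        + "AUAUAUAUAU"
        + au_arm + "CCCCC" + revcomp(au_arm)
    )
    return construct, 0, {"expected_fail": {"hairpin"}}


_BUILDERS = {
    "conforming": _build_conforming,
    "gc": _build_gc,
    "loop": _build_loop,
    "mismatch": _build_mismatch,
    "structure": _build_structure,
}


def _verify_locus(
    genome: list[SequenceRecord], locus: PlantedLocus
) -> bool:
    """Run the precursor caller on the planted mature and check the verdicts."""
    hits = map_tag(locus.mature, genome)
    plus = [h for h in hits if h.strand == "+" and h.start == locus.mature_interval.start]
    if len(plus) != 1 or sum(h.strand == "+" for h in hits) != 1:
        return False  # mature not unique on the plus strand: redraw
    cand = call_precursor(locus.mature, plus[0], genome)
    failing = {k for k, v in cand.verdicts.items() if not v}
    expected = {k for k, v in locus.conforms.items() if not v}
    return failing == expected


def make_reference(
    n_conforming: int = 10,
    n_violators: int = 3,
    genome_len: int = 50_000,
    gc_background: float = 0.45,
    seed: int = 0,
    reference_depth: int = 200_000,
    violation_kinds: Sequence[str] | None = None,
) -> tuple[list[SequenceRecord], TruthManifest]:
    """Build a synthetic genome with planted hairpin loci and its manifest.

    Loci are spaced so that no extraction window of one locus can reach
    another.  Conforming loci are assigned default drought fold changes
    (first three 4x up, next two 4x down, the rest null); violators are null.
    Identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(seed)
    if violation_kinds is None:
        violation_kinds = [VIOLATION_KINDS[i % len(VIOLATION_KINDS)] for i in range(n_violators)]
    if len(violation_kinds) != n_violators:
        raise ValueError("violation_kinds length must equal n_violators")
    kinds = ["conforming"] * n_conforming + list(violation_kinds)

    spacing = HAIRPIN_LEN + 320
    needed = 600 + len(kinds) * spacing
    if needed > genome_len:
        raise ValueError(
            f"genome_len {genome_len} too small for {len(kinds)} loci (need >= {needed})"
        )

    background = list(_random_seq(rng, genome_len, gc_background))
    genome_chars = background[:]
    manifest = TruthManifest(
        seed=int(seed),
        genome_len=int(genome_len),
        gc_background=float(gc_background),
        reference_depth=int(reference_depth),
        adaptor=DEFAULT_ADAPTOR,
    )

    cursor = 300
    n_up, n_down = 3, 2
    conf_idx = 0
    for idx, kind in enumerate(kinds):
        gap = int(rng.integers(40, 120))
        pos = cursor + gap
        builder = _BUILDERS[kind]
        for attempt in range(30):
            construct, mature_off, meta = builder(rng)
            genome_chars[pos : pos + len(construct)] = list(construct)
            genome = [SequenceRecord("chr1", "".join(genome_chars))]
            mature = construct[mature_off : mature_off + MATURE_LEN]
            conforms = {
                crit: crit not in meta["expected_fail"]
                for crit in ("hairpin", "mature_in_arm", "star_mm_le6", "mfe_negative", "gc_in_range")
            }
            if kind == "conforming":
                fc = 4.0 if conf_idx < n_up else (0.25 if conf_idx < n_up + n_down else 1.0)
            else:
                fc = 1.0
            locus = PlantedLocus(
                locus_id=f"locus{idx:02d}_{kind}",
                kind=kind,
                interval=GenomicInterval("chr1", pos, pos + len(construct)),
                mature_interval=GenomicInterval(
                    "chr1", pos + mature_off, pos + mature_off + MATURE_LEN
                ),
                mature=mature,
                star=revcomp(mature),
                conforms=conforms,
                abundance=float(np.round(rng.uniform(150, 600), 1)),
                fold_change=fc,
            )
            if _verify_locus(genome, locus):
                manifest.loci.append(locus)
                break
            # restore background before redrawing
            genome_chars[pos : pos + len(construct)] = background[pos : pos + len(construct)]
        else:
            raise RuntimeError(f"could not construct a verified {kind!r} locus")
        if kind == "conforming":
            conf_idx += 1
        cursor = pos + HAIRPIN_LEN + 260

    genome = [SequenceRecord("chr1", "".join(genome_chars))]
    return genome, manifest


# ---------------------------------------------------------------------------
# library simulation


DEFAULT_LIBRARIES = (
    LibraryMeta("HTI", "HT", "irrigated"),
    LibraryMeta("HTD", "HT", "drought"),
    LibraryMeta("LTI", "LT", "irrigated"),
    LibraryMeta("LTD", "LT", "drought"),
)

READ_LEN = 36


def _nb_counts(rng, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; dispersion 0 is exact Poisson."""
    means = np.asarray(means, dtype=float)
    if dispersion <= 0:
        return rng.poisson(means)
    lam = rng.gamma(shape=1.0 / dispersion, scale=means * dispersion)
    return rng.poisson(lam)


def _random_dna(rng, n: int, length: int) -> list[str]:
    letters = np.array(list("ACGT"))
    draws = rng.integers(0, 4, size=(n, length))
    return ["".join(row) for row in letters[draws]]


def simulate_libraries(
    manifest: TruthManifest,
    depth: int = 200_000,
    dispersion: float = 0.1,
    adaptor: str | None = None,
    fc_map: dict[str, float] | None = None,
    seed: int = 0,
    libraries: Sequence[LibraryMeta] | None = None,
    sirna_fraction: float = 0.6,
    sirna_pool_size: int = 200,
) -> dict[str, list[str]]:
    """Simulate raw reads (DNA, fixed 36 nt, 3' adaptor appended) per library.

    Planted-locus counts are negative-binomial around
    ``abundance * fold_change * depth / reference_depth`` (fold change applies
    to drought libraries); the remaining depth is background: 60 % siRNA-like
    24-mers from a shared weighted pool and 40 % uniform 19-24 nt degradation
    tags.  Identical ``(manifest, seed)`` give identical read lists.
    """
    if adaptor is None:
        adaptor = manifest.adaptor
    adaptor_dna = adaptor.translate(_RNA2DNA)
    if libraries is None:
        libraries = [LibraryMeta(m.name, m.cultivar, m.condition) for m in DEFAULT_LIBRARIES]
    fc_map = fc_map or {}

    pool_rng = np.random.default_rng(manifest.seed + 10_007)
    sirna_pool = _random_dna(pool_rng, sirna_pool_size, 24)
    weights = 1.0 / np.arange(1, sirna_pool_size + 1)
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    scale = depth / manifest.reference_depth

    def make_read(insert_dna: str) -> str:
        return (insert_dna + adaptor_dna)[:READ_LEN]

    out: dict[str, list[str]] = {}
    for lib in libraries:
        means = []
        for locus in manifest.loci:
            fc = fc_map.get(locus.locus_id, locus.fold_change)
            mean = locus.abundance * scale
            if lib.condition == "drought":
                mean *= fc
            means.append(mean)
        counts = _nb_counts(rng, np.array(means), dispersion)
        reads: list[str] = []
        for locus, count in zip(manifest.loci, counts):
            read = make_read(locus.mature.translate(_RNA2DNA))
            reads.extend([read] * int(count))
        background_total = max(0, depth - int(counts.sum()))
        n_sirna = int(round(sirna_fraction * background_total))
        n_degr = background_total - n_sirna
        pool_counts = rng.multinomial(n_sirna, weights)
        for tag, count in zip(sirna_pool, pool_counts):
            if count:
                reads.extend([make_read(tag)] * int(count))
        lengths = rng.integers(19, 25, size=n_degr)
        for length in range(19, 25):
            n_len = int((lengths == length).sum())
            if n_len:
                reads.extend(make_read(s) for s in _random_dna(rng, n_len, length))
        out[lib.name] = reads
    return out


def write_library_fastq(reads: Sequence[str], name: str, path: str | Path) -> None:
    from .io import write_fastq

    write_fastq(((f"{name}_{i}", seq) for i, seq in enumerate(reads, start=1)), path)


# ---------------------------------------------------------------------------
# recovery studies against the manifest


def recover_precursors(
    genome: Sequence[SequenceRecord], manifest: TruthManifest
) -> dict[str, dict]:
    """Re-call every planted locus and report acceptance + failing criteria."""
    out = {}
    for locus in manifest.loci:
        hit = locus.mature_interval
        cand = call_precursor(locus.mature, hit, genome)
        out[locus.locus_id] = {
            "kind": locus.kind,
            "accepted": cand.accepted,
            "failing": sorted(k for k, v in cand.verdicts.items() if not v),
            "expected_failing": sorted(k for k, v in locus.conforms.items() if not v),
            "duplex_mismatches": cand.duplex_mismatches,
        }
    return out


def _tags_from_reads(reads: Sequence[str], adaptor: str):
    rna_reads = (r.translate(_DNA2RNA) for r in reads)
    return preprocess_reads(rna_reads, adaptor=adaptor)


def de_recovery_once(
    manifest: TruthManifest,
    seed: int,
    depth: int = 200_000,
    dispersion: float = 0.0,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
) -> dict[str, dict]:
    """Simulate one irrigated/drought pair, run the pipeline, call DE per locus.

    Uses the Poisson calibration mode of the generator by default (see the
    methods note: the pooled count statistic is exact under Poisson sampling,
    which is what a recovery study of the calling logic should assume).
    """
    libs = [LibraryMeta("HTI", "HT", "irrigated"), LibraryMeta("HTD", "HT", "drought")]
    reads = simulate_libraries(
        manifest, depth=depth, dispersion=dispersion, seed=seed, libraries=libs
    )
    counters = {}
    for lib in libs:
        counters[lib.name], _ = _tags_from_reads(reads[lib.name], manifest.adaptor)
    table = collapse_tags(counters, libs)
    n1 = table.library("HTI").total_clean_reads
    n2 = table.library("HTD").total_clean_reads
    results = {}
    for locus in manifest.loci:
        tag = locus.mature
        x = int(table.counts.at[tag, "HTI"]) if tag in table.counts.index else 0
        y = int(table.counts.at[tag, "HTD"]) if tag in table.counts.index else 0
        res = call_de(x, y, n1, n2, feature_id=locus.locus_id,
                      alpha=alpha, fc_threshold=fc_threshold)
        expected = (
            "up" if locus.fold_change >= fc_threshold
            else "down" if locus.fold_change <= 1.0 / fc_threshold
            else "unchanged"
        )
        results[locus.locus_id] = {
            "direction": res.direction,
            "expected": expected,
            "correct": res.direction == expected,
            "p_value": res.p_value,
            "fold_change": res.fold_change,
        }
    return results


def de_recovery_study(
    manifest: TruthManifest,
    n_seeds: int = 50,
    base_seed: int = 1,
    depth: int = 200_000,
    dispersion: float = 0.0,
) -> tuple[float, list[bool]]:
    """Fraction of simulation seeds where every planted locus is called
    correctly (all true DE loci recovered with the right direction, no null
    locus called)."""
    outcomes = []
    for k in range(n_seeds):
        results = de_recovery_once(
            manifest, seed=base_seed + k, depth=depth, dispersion=dispersion
        )
        outcomes.append(all(r["correct"] for r in results.values()))
    return sum(outcomes) / len(outcomes), outcomes
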