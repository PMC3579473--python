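"""miRNA target prediction by complementarity expectation scoring.

A miRNA recognises a transcript site by near-perfect antisense
complementarity.  The expectation score sums per-position penalties over the
miRNA:site duplex - 0 for a Watson-Crick pair, 0.5 for a G:U wobble, 1 for a
mismatch, with configurable gap penalties and an optional seed-region
multiplier - so 0 is a perfect alignment and larger is worse.  Sites are
reported with 1-based inclusive transcript coordinates and both aligned
fragments written 5'->3'.

Site accessibility is summarized by an approximate opening energy (UPE): the
score lost when the site's positions are forbidden from pairing in the local
fold.  It uses the package's own pair-score model, so its values are
comparable between sites scored here but not to thermodynamic
partition-function energies from other tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import fold as _fold
from .records import GenomicInterval, SequenceRecord

MATCH = "match"
GU = "GU"
MISMATCH = "mismatch"
GAP = "gap"

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def pair_class(mirna_base: str, target_base: str) -> str:
    """Classify one miRNA:target base opposition; N is always a mismatch."""
    duo = (mirna_base, target_base)
    if duo in _WC:
        return MATCH
    if duo in _WOBBLE:
        return GU
    return MISMATCH


@dataclass(frozen=True)
class ScoreScheme:
    """Penalty scheme for expectation scoring.

    ``seed_interval`` (1-based inclusive positions from the miRNA 5' end) and
    ``seed_multiplier`` enable psRNATarget-style seed weighting; the default
    scheme applies no seed weighting because the worked alignment examples
    bundled with the package are all reproduced exactly by the plain
    {mismatch 1, G:U 0.5} penalties.
    """

    mismatch: float = 1.0
    gu_wobble: float = 0.5
    gap_open: float = 2.0
    gap_extend: float = 0.5
    seed_interval: tuple[int, int] | None = None
    seed_multiplier: float = 1.0
    max_expectation: float = 5.0

    def __post_init__(self) -> None:
        if min(self.mismatch, self.gu_wobble, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")
        if self.seed_multiplier < 1.0:
            raise ValueError("seed multiplier must be >= 1")

    def position_weight(self, mirna_pos: int) -> float:
        """Multiplier for a 0-based miRNA position."""
        if self.seed_interval is None:
            return 1.0
        lo, hi = self.seed_interval
        return self.seed_multiplier if lo <= mirna_pos + 1 <= hi else 1.0


DEFAULT_SCHEME = ScoreScheme()


def expectation_score(
    mirna_fragment: str,
    target_fragment: str,
    scheme: ScoreScheme = DEFAULT_SCHEME,
) -> tuple[float, list[str]]:
    """Score an ungapped miRNA:target alignment, both fragments 5'->3'.

    miRNA position ``i`` faces target position ``L-1-i`` (the duplex is
    antiparallel).  Returns the summed penalty and per-miRNA-position labels.
    """
    if len(mirna_fragment) != len(target_fragment):
        raise ValueError(
            "ungapped scoring needs equal-length fragments "
            f"({len(mirna_fragment)} vs {len(target_fragment)})"
        )
    L = len(mirna_fragment)
    score = 0.0
    labels = []
    for i in range(L):
        cls = pair_class(mirna_fragment[i], target_fragment[L - 1 - i])
        labels.append(cls)
        if cls == GU:
            score += scheme.gu_wobble * scheme.position_weight(i)
        elif cls == MISMATCH:
            score += scheme.mismatch * scheme.position_weight(i)
    return score, labels


def _gapped_score(
    mirna: str, window: str, scheme: ScoreScheme
) -> tuple[float, list[str]] | None:
    """Best single-indel alignment of the miRNA against a window of length
    ``len(mirna) +/- 1``; None when the window length is unsupported."""
    L, W = len(mirna), len(window)
    target = window[::-1]  # miRNA i faces reversed-target i
    gap_cost = scheme.gap_open  # single indel: open only

    def ungapped_cost(mi: Iterable[int], ti: Iterable[int]) -> tuple[float, list[str]]:
        s, lab = 0.0, []
        for i, j in zip(mi, ti):
            cls = pair_class(mirna[i], target[j])
            lab.append(cls)
            if cls == GU:
                s += scheme.gu_wobble * scheme.position_weight(i)
            elif cls == MISMATCH:
                s += scheme.mismatch * scheme.position_weight(i)
        return s, lab

    best: tuple[float, list[str]] | None = None
    if W == L - 1:  # one miRNA base bulged (gap in target)
        for g in range(L):
            mi = [i for i in range(L) if i != g]
            s, lab = ungapped_cost(mi, range(W))
            s += gap_cost
            lab = lab[:g] + [GAP] + lab[g:]
            if best is None or s < best[0]:
                best = (s, lab)
    elif W == L + 1:  # one target base bulged
        for g in range(W):
            ti = [j for j in range(W) if j != g]
            s, lab = ungapped_cost(range(L), ti)
            s += gap_cost
            if best is None or s < best[0]:
                best = (s, lab)
    elif W == L:
        s, lab = expectation_score(mirna, window, scheme)
        best = (s, lab)
    return best


@dataclass(frozen=True)
class TargetHit:
    """One predicted miRNA target site on a transcript."""

    mirna_id: str
    transcript_id: str
    site: GenomicInterval  # on the transcript, plus strand
    mirna_fragment: str
    target_fragment: str
    expectation: float
    upe: float | None
    alignment: tuple[str, ...] = field(default=())


def scan_transcripts(
    mirna: SequenceRecord,
    transcripts: Sequence[SequenceRecord],
    scheme: ScoreScheme = DEFAULT_SCHEME,
    max_expectation: float | None = None,
    gapped: bool = False,
    compute_upe: bool = False,
    upe_flank: int = 17,
) -> list[TargetHit]:
    """Slide the miRNA over every transcript and keep low-expectation sites.

    Ungapped windows of miRNA length are always scored; with ``gapped`` the
    +/-1-length windows with a single indel are scored too.  Hits with
    expectation <= the scheme's cap are returned sorted by
    (expectation, transcript id, start).
    """
    if max_expectation is None:
        max_expectation = scheme.max_expectation
    L = len(mirna.sequence)
    hits = []
    for tx in transcripts:
        seq = tx.sequence
        lengths = (L,) if not gapped else (L, L - 1, L + 1)
        for wlen in lengths:
            if wlen < 1:
                continue
            for start in range(0, len(seq) - wlen + 1):
                window = seq[start : start + wlen]
                if wlen == L:
                    score, labels = expectation_score(mirna.sequence, window, scheme)
                else:
                    res = _gapped_score(mirna.sequence, window, scheme)
                    if res is None:
                        continue
                    score, labels = res
                if score > max_expectation:
                    continue
                site = GenomicInterval(tx.id, start, start + wlen)
                upe = (
                    upe_approx(seq, (start, start + wlen), flank=upe_flank)
                    if compute_upe
                    else None
                )
                hits.append(
                    TargetHit(
                        mirna_id=mirna.id,
                        transcript_id=tx.id,
                        site=site,
                        mirna_fragment=mirna.sequence,
                        target_fragment=window,
                        expectation=score,
                        upe=upe,
                        alignment=tuple(labels),
                    )
                )
    hits.sort(key=lambda h: (h.expectation, h.transcript_id, h.site.start))
    return hits


def upe_approx(
    transcript: str, site: tuple[int, int], flank: int = 17
) -> float:
    """Approximate energy to open the target site's local structure.

    The site +/- ``flank`` region is folded twice - unconstrained, then with
    the site's positions forbidden from pairing - and the UPE is the score
    difference (>= 0).  Model-score units; see the module docstring.
    """
    s, e = site
    if not (0 <= s < e <= len(transcript)):
        raise ValueError(f"site {site} outside transcript of length {len(transcript)}")
    lo = max(0, s - flank)
    hi = min(len(transcript), e + flank)
    region = transcript[lo:hi]
    free = _fold.fold(region)
    blocked = set(range(s - lo, e - lo))
    constrained = _fold.fold(region, blocked=blocked)
    return float(constrained.energy - free.energy)


def hits_to_frame(hits: Sequence[TargetHit]):
    """Tabulate hits with 1-based inclusive coordinates."""
    import pandas as pd

    return pd.DataFrame(
        {
            "mirna": [h.mirna_id for h in hits],
            "transcript": [h.transcript_id for h in hits],
            "expectation": [h.expectation for h in hits],
            "upe": [h.upe for h in hits],
            "target_start": [h.site.start1 for h in hits],
            "target_end": [h.site.end1 for h in hits],
            "mirna_fragment": [h.mirna_fragment for h in hits],
            "target_fragment": [h.target_fragment for h in hits],
        }
    )
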