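# Methods

`canemir` analyses small-RNA sequencing tag libraries from sugarcane leaves to
find drought-responsive miRNAs: it cleans and collapses raw reads, assigns
tags to annotation categories, calls hairpin precursor loci around mapped
miRNA tags, tests per-tag expression differences between pooled
irrigated/drought libraries, and scans transcripts for miRNA target sites.
This note records the models, the parameters that matter, and the design
decisions taken where the problem was genuinely open.

## Tag preprocessing

Reads are single-end, fixed-length sequencer output carrying a 3' adaptor.
The adaptor is located by exact prefix match: the leftmost position at which
a prefix of the adaptor (length ≥ `min_overlap`, default 6 nt) matches the
read with zero mismatches (one mismatch optionally) marks the insert
boundary; the match and everything 3' of it is removed. Exactness keeps the
operation deterministic and idempotent; no published trimming heuristic is
emulated. Reads in which no adaptor is found are retained whole and flagged
(they may be full-length inserts; a switch discards them), reads that are
pure adaptor are dropped. Inserts outside 19–24 nt — the biological size
range of plant sRNA regulators — are discarded; the wider size selection
applied at the bench is a wet-lab concern and plays no computational role.
Clean reads are collapsed to unique tags with one count column per library;
per-library column sums define the library totals used by every
normalization downstream.

When a tag matches several reference classes, categories are assigned with
the fixed precedence miRNA > rRNA > tRNA > snRNA > snoRNA > siRNA >
Unannotated, which makes the category partition well defined; structural
classes require an exact substring hit in a user-supplied per-class FASTA
(no remote database dependency), miRNA requires a mature match (below), and
the siRNA label is reserved for 24-nt tags with genome-mapping evidence —
without a genome that class is unreachable and such tags fall to
Unannotated.

## Known-mature matching

Tags are compared to a bundled set of 30 sugarcane mature miRNAs (18
families) by ungapped alignment with at most 2 mismatches, the conventional
cross-species matching budget. End shifts of up to ±2 nt are examined so
that isomiR-like length/register variants still match (positions sliding off
the reference count as mismatches); `shift=0` recovers the strict
fixed-register mode, since published analyses rarely state which convention
they used. Ties break by fewer mismatches, then smaller shift, then
reference id, so matching is deterministic.

## Secondary structure model

Precursor calling needs three structural signals — is the fold a single
stem-loop, is the fold energy negative, where does each base pair — none of
which requires thermodynamic accuracy. The folder is therefore a
Nussinov-style dynamic programme over weighted pairs (G:C −3, A:U −2, G:U
−1, minimum hairpin loop 3 nt) minimizing the total score. Energies are
model scores: they share the sign convention of a free energy (0 iff no pair
forms) but are *not* comparable to kcal/mol from thermodynamic folders;
downstream logic only uses the sign and the pair map. Traceback is
deterministic — the leftmost base of every subproblem pairs its outermost
compatible partner whenever optimal — so structures are reproducible.
For sequences up to 12 nt the DP is verified against exhaustive enumeration
of every loop-legal structure; a sanity cross-check against a
thermodynamic folder (when its bindings are importable) compares structures
and energy signs only, never absolute energies.

A fold counts as a hairpin only when its pairs form one nested chain (no two
pairs side by side anywhere): internal loops and bulges are allowed,
branches are not. The loop is the region enclosed by the innermost pair and
the arms run from the outermost pair to the innermost on each side.

## Precursor calling

Each miRNA tag is mapped to the reference by exact ungapped search on both
strands. For every hit a 250-nt window — the window size the plant
precursor literature settled on — is extracted and folded. Because the
excision register of the true precursor around a mapped read is not
observable, three placements are folded (tag centred, tag at the window's 5'
end, tag at its 3' end) and the best-scoring accepted placement is kept;
when none is accepted the placement that looks most precursor-like
(criteria compared in order: hairpin geometry, mature placement, duplex
mismatches, energy sign, GC) is reported so the failing verdicts describe
the most informative window. Acceptance requires all of:

1. the window folds into a single stem-loop hairpin;
2. the mature tag lies entirely within one arm;
3. the mature has at most 6 mismatches with its star partner in the
   opposite arm (mature positions with no partner there, counted once each);
4. the fold energy is strictly negative;
5. window GC content lies in [30, 70] % (bounds inclusive).

The star span is the set of positions paired with the mature, extended by
the conventional 2-nt 3' offset. A star read among the sequenced tags is
not required — most datasets lack many stars, and the criterion list above
does not demand observation. Multi-mapping tags produce one candidate per
hit, deduplicated at ≥ 80 % window overlap (a hairpin and its reverse
complement describe the same locus, so strand is ignored when
deduplicating).

## Differential expression

Libraries are pooled per cultivar × condition, so the statistic is defined
on one count per condition. For a tag with ``x`` counts among ``n1`` clean
reads and ``y`` among ``n2``, the Audic–Claverie model gives

    P(y | x) = (n2/n1)^y (x+y)! / ( x! y! (1 + n2/n1)^(x+y+1) )

Tails are summed in log space (log-gamma + log-sum-exp; the infinite upper
tail is truncated once whole summation chunks fall ~26 natural-log units
below the running maximum) and the two-sided p-value is twice the smaller
of the inclusive tails, capped at 1. The implementation agrees with an
exact `fractions.Fraction` evaluation to better than 1e-10 relative error
over all x, y ≤ 50 at library ratios 0.5–2, and its empirical type-I rate
under equal Poisson rates is ~0.04 at α = 0.05 (conservative, as expected
for a discrete doubled-tail test).

One discreteness subtlety is worth recording: with both tails inclusive,
the doubled-min-tail p-value is *not* exactly symmetric under exchanging
the libraries — the exact identity is
``Σ_{k≤y} P(k|x, n2/n1) = Σ_{k≥x+1} P(k|y, n1/n2)``, so the two orientations
differ by at most the boundary point mass (a strictly symmetric convention
would instead lose the property that x = y gives p = 1). The package fixes
the orientation — ``x`` is always the irrigated/control library — so calls
are well defined, and the tests assert the exact tail-exchange identity and
the boundary-bounded symmetry.

A tag is called differentially expressed when p < 0.05 **and** the
fold-change of pseudocount-adjusted normalized rates
``((y+0.5)/n2) / ((x+0.5)/n1)`` satisfies max(fc, 1/fc) ≥ 2 — the raw-p
calling rule standard in pooled-library DGE studies; no multiple-testing
correction is applied by default, though a Benjamini–Hochberg helper is
available. TPM is 1e6 × count / library total, with total clean reads as
the default denominator (total miRNA-annotated reads would be a defensible
alternative; the choice only rescales both libraries).

## Target prediction

A miRNA recognises a site by antisense complementarity: miRNA position *i*
(5'→3') faces target position *L−1−i*. The expectation score sums
per-position penalties — 0 for Watson–Crick, 0.5 for G:U wobble, 1 for a
mismatch — so 0 is perfect and sites above 5.0 are discarded by default.
The bundled worked alignments are all reproduced exactly by this plain
scheme, so the default applies **no** seed-region weighting; a
psRNATarget-style seed multiplier and a single-indel gapped mode (gap open
2.0) are available but off by default, as every verified example is
ungapped. Scores are additive over positions and invariant under swapping
the two fragments (the same duplex read from the other strand); note that
complementing both fragments is *not* a symmetry once G:U is penalized
differently from a mismatch.

Site accessibility is summarized by an approximate opening energy (UPE):
the site ± 17 nt is folded unconstrained, then refolded with the site's
positions forbidden from pairing, and the UPE is the score difference
(≥ 0). Because it uses the package's own pair-score model, UPE values are
comparable between sites scored here but deliberately not to
partition-function energies printed by thermodynamic tools.

## Synthetic data

The generator emulates the study design: a random background genome
(GC 0.45) carrying planted 250-nt hairpin loci — perfect inverted repeats
(121-bp arms, 8-nt A/C loop that cannot pair internally) with a 21-nt
mature at the 5' end of the 5' arm and the star offset 2 nt at the 3'
ends — and two-cultivar × two-condition libraries of 36-nt adaptor-carrying
reads. Designated violator loci break exactly one acceptance criterion:
GC-rich arms (~83 % GC), a mature spanning the loop (placed so the centred
window is exactly the planted hairpin), seven C:C oppositions in the mature
region (> 6 duplex mismatches), or two disjoint stems built from
non-interacting alphabets (no single hairpin exists). Every planted locus
is verified against the precursor caller at construction time and redrawn
from the same seeded stream in the rare event a traceback tie breaks the
intended verdict pattern, so the truth manifest is guaranteed rather than
probable. Generation is byte-deterministic per seed.

Library counts per locus are negative-binomial (gamma–Poisson) around
abundance × fold-change × depth, with default dispersion 0.1 and abundances
uniform in [150, 600] expected counts at the reference depth of 200k
reads/library; the default fold-change map plants three 4× up-regulated
loci, two 4× down-regulated, and leaves the rest (including all violators)
null. Background reads are 60 % siRNA-like 24-mers drawn from a shared
weighted pool and 40 % uniform 19–24-nt degradation tags, which together
with the 21-nt planted matures reproduce the bimodal 21/24-nt size
distribution characteristic of plant sRNA libraries.

The end-to-end DE recovery study (50 simulation seeds on one fixed
reference, irrigated vs drought at 200k reads/library) runs the generator
in its Poisson calibration mode (dispersion 0). The reasoning is a priori:
the pooled Audic–Claverie statistic models Poisson sampling of a fixed
rate, so a recovery study of the *calling logic* should satisfy that
assumption; under dispersion 0.1 the pooled test is intrinsically
anti-conservative (log2 fold-change noise sd ≈ √(2·0.1)/ln 2 ≈ 0.65 at
these abundances, so a null locus crosses the FC ≥ 2 gate ~12 % of the
time and a 4× locus is missed ~6 % of the time, independent of depth).
A separate test documents that overdispersion inflates count variance as
modelled; robustness of pooled DGE calling to overdispersion is a known
limitation of the method itself, not of this implementation.

What passing these simulations does **not** show about real data: the
generator has no sequencing errors, no quality-score structure, no isomiRs,
no genomic repeat structure (each mature maps uniquely), and perfect
duplexes in conforming loci; real precursors have bulged, imperfect stems
and real libraries are overdispersed between biological replicates.

## Problem sizes and numerical choices

Defaults throughout: 10 conforming + 3 violator loci on a 50-kb genome;
200k reads/library; 50 seeds in the recovery study; the folding oracle is
checked on 200 random sequences ≤ 12 nt (exhaustive enumeration above that
length is combinatorial); the count-statistic oracle grid is x, y ≤ 50 at
library ratios {0.5, 1, 2}. Pair scores are integers, so DP energies are
exact; p-values within one part in 1e12 of 1 are clamped to 1 to absorb
final-ulp rounding of the log-space sums at the symmetric point. The
Nussinov fill uses an optional numba kernel with a pure-numpy fallback that
produces identical integer tables.

## Known limitations

- The fold model ignores stacking, dangles and temperature; its energies
  gate a sign test only.
- UPE values are in model units and not comparable to published
  accessibility energies.
- The pooled two-library test cannot model biological replicate variance;
  with replicates available, a dispersion-modelling DE framework is the
  right tool.
- Target prediction is complementarity-only; no degradome or conservation
  evidence is used.
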