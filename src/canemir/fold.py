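"""Lightweight RNA secondary-structure prediction.

A Nussinov-style dynamic programme over a weighted pair model: each base pair
contributes a fixed score (G:C -3, A:U -2, G:U -1), hairpin loops must
enclose at least three unpaired bases, and the optimum is the structure of
minimum total score.  Energies are therefore *model scores* with the sign
convention of a free energy — negative iff at least one pair forms — and are
deliberately not comparable to thermodynamic kcal/mol values: downstream the
energy only gates a sign test and a duplex-geometry test.

Traceback is deterministic: the leftmost base of each subproblem pairs its
outermost compatible partner whenever doing so is optimal, so repeated runs
produce byte-identical structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import RNA_ALPHABET

MIN_LOOP = 3

#: pair scores; anything absent cannot pair (N never pairs)
PAIR_SCORES: dict[tuple[str, str], int] = {
    ("G", "C"): -3, ("C", "G"): -3,
    ("A", "U"): -2, ("U", "A"): -2,
    ("G", "U"): -1, ("U", "G"): -1,
}

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_SCORE5 = np.zeros((5, 5), dtype=np.int64)
for (_a, _b), _s in PAIR_SCORES.items():
    _SCORE5[_CODE[_a], _CODE[_b]] = _s


@dataclass(frozen=True)
class FoldResult:
    """One optimal structure of a single sequence."""

    sequence: str
    structure: str
    energy: float
    pair_map: tuple[int | None, ...]

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-RNA character {exc.args[0]!r}") from exc


def _pair_weights(codes: np.ndarray, blocked: np.ndarray | None) -> np.ndarray:
    w = _SCORE5[codes[:, None], codes[None, :]]
    if blocked is not None:
        w[blocked, :] = 0
        w[:, blocked] = 0
    return w


def _fill_python(w: np.ndarray, min_loop: int) -> np.ndarray:
    """Vectorized DP fill used when numba is unavailable."""
    n = w.shape[0]
    N = np.zeros((n + 2, n + 2), dtype=np.int64)  # N[i, j], padded
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j]
            ks = np.arange(i + min_loop + 1, j + 1)
            wk = w[i, ks]
            cand = wk + N[i + 1, ks - 1] + N[ks + 1, j]
            cand = cand[wk < 0]
            if cand.size:
                best = min(best, int(cand.min()))
            N[i, j] = best
    return N


try:  # optional acceleration; identical results
    from numba import njit

    @njit(cache=True)
    def _fill_numba(w, min_loop):  # pragma: no cover - thin jit kernel
        n = w.shape[0]
        N = np.zeros((n + 2, n + 2), dtype=np.int64)
        for span in range(min_loop + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = N[i + 1, j]
                for k in range(i + min_loop + 1, j + 1):
                    if w[i, k] < 0:
                        v = w[i, k] + N[i + 1, k - 1] + N[k + 1, j]
                        if v < best:
                            best = v
                N[i, j] = best
        return N

    _FILL = _fill_numba
except ImportError:  # pragma: no cover
    _FILL = _fill_python


def fold(sequence: str, blocked: set[int] | None = None, min_loop: int = MIN_LOOP) -> FoldResult:
    """Fold one sequence, returning an optimal structure and its score.

    ``blocked`` positions are forbidden from pairing (used for target-site
    opening energies).  The dot-bracket string, the pair map and the energy
    are mutually consistent; ``energy == 0`` iff no pair forms.
    """
    if not sequence:
        raise ValueError("cannot fold an empty sequence")
    if not set(sequence) <= RNA_ALPHABET:
        raise ValueError("sequence must be canonical RNA (A/C/G/U/N)")
    n = len(sequence)
    codes = _encode(sequence)
    mask = None
    if blocked:
        mask = np.zeros(n, dtype=bool)
        mask[list(blocked)] = True
    w = _pair_weights(codes, mask)
    N = _FILL(w, min_loop)

    pair_map: list[int | None] = [None] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = N[i, j]
        paired = False
        # outermost compatible partner first, leftmost base first
        for k in range(j, i + min_loop, -1):
            if w[i, k] < 0 and w[i, k] + N[i + 1, k - 1] + N[k + 1, j] == target:
                pair_map[i] = k
                pair_map[k] = i
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))

    structure = "".join(
        "." if p is None else ("(" if p > i else ")") for i, p in enumerate(pair_map)
    )
    energy = float(N[0, n - 1]) if n > 1 else 0.0
    return FoldResult(sequence, structure, energy, tuple(pair_map))


def enumerate_structures(sequence: str, min_loop: int = MIN_LOOP):
    """Yield every loop-legal structure (as a frozenset of pairs).

    Exhaustive decomposition by the fate of the leftmost base; intended as an
    independent oracle on short sequences, not for production folding.
    """
    codes = _encode(sequence)
    w = _pair_weights(codes, None)
    n = len(sequence)

    memo: dict[tuple[int, int], list[frozenset]] = {}

    def region(i: int, j: int) -> list[frozenset]:
        if j - i <= min_loop:
            return [frozenset()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [frozenset({(i, k)} | a | b)
               for k in range(i + min_loop + 1, j + 1)
               if w[i, k] < 0
               for a in region(i + 1, k - 1)
               for b in region(k + 1, j)]
        out.extend(region(i + 1, j))
        memo[key] = out
        return out

    yield from region(0, n - 1)


def best_energy_exhaustive(sequence: str, min_loop: int = MIN_LOOP) -> float:
    """Minimum score over *all* loop-legal structures, by brute enumeration."""
    codes = _encode(sequence)
    w = _pair_weights(codes, None)
    best = 0
    for pairs in enumerate_structures(sequence, min_loop=min_loop):
        score = sum(int(w[i, k]) for i, k in pairs)
        best = min(best, score)
    return float(best)


def gc_content(sequence: str) -> float:
    """G/C percentage of a sequence (0-100)."""
    if not sequence:
        raise ValueError("gc_content of empty sequence is undefined")
    gc = sequence.count("G") + sequence.count("C")
    return 100.0 * gc / len(sequence)


def arms_of(
    result: FoldResult,
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None:
    """Decompose a fold into (5' arm, loop, 3' arm) half-open spans.

    Returns ``None`` ("not a hairpin") unless the pairs form one nested stem:
    no two pairs may sit side by side anywhere in the structure (internal
    loops and bulges are allowed, branches are not).  The loop is the region
    enclosed by the innermost pair; the arms run from the outermost pair to
    the innermost on each side.
    """
    pairs = sorted((i, p) for i, p in enumerate(result.pair_map) if p is not None and p > i)
    if not pairs:
        return None
    for t in range(1, len(pairs)):
        # sorted by i; nesting requires strictly decreasing j
        if pairs[t][1] > pairs[t - 1][1]:
            return None
    outer_i, outer_j = pairs[0]
    inner_i, inner_j = pairs[-1]
    five = (outer_i, inner_i + 1)
    loop = (inner_i + 1, inner_j)
    three = (inner_j, outer_j + 1)
    return five, loop, three
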