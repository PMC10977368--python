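"""RNA secondary structure and per-base accessibility (ss-count) profiles.

AON accessibility screening asks a simple question of the target region: how
often is each base single-stranded across an ensemble of plausible secondary
structures?  The classic workflow folds the region, requests suboptimal
structures, and reads off an "ss count" per base; windows with high mean
openness are preferred AON landing sites.

The folder implemented here is a stacking-weighted Nussinov-style dynamic
program over nested (pseudoknot-free) structures with Watson-Crick and G:U
pairing and a minimum hairpin loop of 3 nt.  Structure score =

    sum over pairs of a pair weight (GC=3, AU=2, GU=1)
    + a bonus of 1 for every stacked pair (i,j),(i+1,j-1)

This is a deliberate stand-in for a full thermodynamic folder: it is exact,
deterministic, and small enough to verify against exhaustive enumeration,
while an external engine can be slotted in behind the same two functions for
users who want Turner-model ensembles.  Suboptimal structures are generated
by pair-exclusion refolds: forbid one base pair of the optimal structure and
refold, keeping distinct structures whose score stays within a tolerance of
the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

PAIR_WEIGHTS = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "U"): 2.0, ("U", "A"): 2.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}
STACK_BONUS = 1.0
DEFAULT_MIN_LOOP = 3
DEFAULT_ENSEMBLE_SIZE = 10
DEFAULT_SUBOPT_TOLERANCE = 0.95

_RNA_BASES = frozenset("ACGU")


class FoldingError(ValueError):
    pass


def to_rna(sequence: str) -> str:
    """Uppercase and transcribe T to U (annotation supplies DNA)."""
    return sequence.upper().replace("T", "U")


@dataclass(frozen=True)
class SecondaryStructure:
    """One nested structure: base pairs, dot-bracket rendering, score."""

    pairs: frozenset[tuple[int, int]]
    dotbracket: str
    score: float

    def unpaired_mask(self) -> np.ndarray:
        mask = np.ones(len(self.dotbracket), dtype=bool)
        for i, j in self.pairs:
            mask[i] = mask[j] = False
        return mask


@dataclass(frozen=True)
class SSCountProfile:
    """Per-base fraction of ensemble structures in which a base is unpaired."""

    openness: np.ndarray
    n_structures: int

    def __post_init__(self):
        if np.any(self.openness < 0) or np.any(self.openness > 1):
            raise FoldingError("openness values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.openness)

    def mean_openness(self, start: int, end: int) -> float:
        if not 0 <= start < end <= len(self.openness):
            raise ValueError(f"window [{start},{end}) out of profile bounds")
        return float(self.openness[start:end].mean())

    def to_tsv(self, sequence: str) -> str:
        """Tab-delimited (position, base, openness) — the ss-count table."""
        lines = ["position\tbase\topenness"]
        rna = to_rna(sequence)
        for i, (b, o) in enumerate(zip(rna, self.openness)):
            lines.append(f"{i}\t{b}\t{o:.4f}")
        return "\n".join(lines) + "\n"


def _check_rna(seq: str) -> str:
    rna = to_rna(seq)
    bad = set(rna) - _RNA_BASES
    if bad:
        raise FoldingError(f"invalid bases for folding: {sorted(bad)}")
    if len(rna) < 1:
        raise FoldingError("empty sequence")
    return rna


def fold_mfe(
    sequence: str,
    min_loop: int = DEFAULT_MIN_LOOP,
    forbidden_pairs: frozenset[tuple[int, int]] = frozenset(),
) -> SecondaryStructure:
    """Maximum-score nested structure; deterministic for fixed input.

    ``forbidden_pairs`` supports the pair-exclusion refolds used for the
    suboptimal ensemble.
    """
    rna = _check_rna(sequence)
    n = len(rna)

    pw = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if (i, j) in forbidden_pairs:
                continue
            w = PAIR_WEIGHTS.get((rna[i], rna[j]))
            if w is not None:
                pw[i, j] = w

    NEG = -np.inf
    # Half-open intervals: W[i][j] = best score of rna[i:j];
    # V[i][j] = best score of rna[i:j] with (i, j-1) paired.
    W = np.zeros((n + 2, n + 2))
    V = np.full((n + 2, n + 2), NEG)
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            if pw[i, j - 1] > NEG:
                inner = W[i + 1, j - 1]
                if V[i + 1, j - 1] > NEG:
                    inner = max(inner, V[i + 1, j - 1] + STACK_BONUS)
                V[i, j] = pw[i, j - 1] + inner
            best = W[i + 1, j]
            m_lo = i + min_loop + 2  # m = k+1 where k pairs with i
            if m_lo <= j:
                cand = V[i, m_lo : j + 1] + W[m_lo : j + 1, j].ravel()
                best = max(best, float(np.max(cand)))
            W[i, j] = best

    pairs: set[tuple[int, int]] = set()
    _traceback(W, V, pw, pairs, 0, n, min_loop)
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return SecondaryStructure(
        pairs=frozenset(pairs), dotbracket="".join(db), score=float(W[0, n])
    )


def _traceback(W, V, pw, pairs, i, j, min_loop, as_V=False):
    """Recover one optimal structure (leftmost-unpaired-first tie-break)."""
    if j - i < 2:
        return
    if as_V:
        k = j - 1  # (i, k) paired
        pairs.add((i, k))
        target = V[i, j] - pw[i, k]
        if V[i + 1, j - 1] > -np.inf and np.isclose(
            target, V[i + 1, j - 1] + STACK_BONUS
        ):
            _traceback(W, V, pw, pairs, i + 1, j - 1, min_loop, as_V=True)
        else:
            _traceback(W, V, pw, pairs, i + 1, j - 1, min_loop)
        return
    if np.isclose(W[i, j], W[i + 1, j]):
        _traceback(W, V, pw, pairs, i + 1, j, min_loop)
        return
    for m in range(i + min_loop + 2, j + 1):
        if V[i, m] > -np.inf and np.isclose(W[i, j], V[i, m] + W[m, j]):
            _traceback(W, V, pw, pairs, i, m, min_loop, as_V=True)
            _traceback(W, V, pw, pairs, m, j, min_loop)
            return
    raise AssertionError("traceback failed to reproduce DP score")


def suboptimal_ensemble(
    sequence: str,
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
    tolerance: float = DEFAULT_SUBOPT_TOLERANCE,
    min_loop: int = DEFAULT_MIN_LOOP,
    max_refolds: int | None = None,
) -> list[SecondaryStructure]:
    """The MFE structure plus up to ``ensemble_size - 1`` suboptimals.

    Each refold forbids one base pair of the optimal structure; structures
    scoring below ``tolerance * mfe_score`` are discarded.  ``max_refolds``
    caps the number of exclusion refolds (default ``3 * ensemble_size``).
    """
    if ensemble_size < 1:
        raise FoldingError(f"ensemble size must be >= 1, got {ensemble_size}")
    mfe = fold_mfe(sequence, min_loop=min_loop)
    structures = [mfe]
    if ensemble_size == 1 or not mfe.pairs:
        return structures
    if max_refolds is None:
        max_refolds = 3 * ensemble_size
    seen = {mfe.dotbracket}
    cutoff = tolerance * mfe.score
    candidates = []
    for p in sorted(mfe.pairs)[:max_refolds]:
        alt = fold_mfe(sequence, min_loop=min_loop, forbidden_pairs=frozenset({p}))
        if alt.dotbracket in seen or alt.score < cutoff:
            continue
        seen.add(alt.dotbracket)
        candidates.append(alt)
    candidates.sort(key=lambda s: (-s.score, s.dotbracket))
    structures.extend(candidates[: ensemble_size - 1])
    return structures


def ss_count_profile(
    sequence: str,
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
    tolerance: float = DEFAULT_SUBOPT_TOLERANCE,
    min_loop: int = DEFAULT_MIN_LOOP,
) -> SSCountProfile:
    """Fraction of ensemble structures in which each base is unpaired.

    With ``ensemble_size=1`` this degenerates to the MFE unpaired indicator.
    """
    ensemble = suboptimal_ensemble(
        sequence, ensemble_size=ensemble_size, tolerance=tolerance,
        min_loop=min_loop,
    )
    masks = np.stack([s.unpaired_mask() for s in ensemble])
    openness = masks.mean(axis=0)
    logger.debug(
        "ss-count over %d structure(s), mean openness %.3f",
        len(ensemble), float(openness.mean()),
    )
    return SSCountProfile(openness=openness, n_structures=len(ensemble))


def enumerate_structures(sequence: str, min_loop: int = DEFAULT_MIN_LOOP):
    """Yield every nested structure (as a frozenset of pairs).

    Exhaustive; intended as an independent oracle for short sequences.
    """
    rna = _check_rna(sequence)
    n = len(rna)

    def pairable(i, j):
        return (rna[i], rna[j]) in PAIR_WEIGHTS and j - i - 1 >= min_loop

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def enum(i, j):  # structures of rna[i:j]
        if j - i < 2:
            return (frozenset(),)
        out = list(enum(i + 1, j))  # i unpaired
        for k in range(i + min_loop + 1, j):
            if pairable(i, k):
                for inner in enum(i + 1, k):
                    for outer in enum(k + 1, j):
                        out.append(inner | outer | {(i, k)})
        return tuple(out)

    yield from enum(0, n)


def score_structure(sequence: str, pairs) -> float:
    """Score a structure by the same weights the DP optimizes (independent
    summation, usable as an oracle against :func:`fold_mfe`)."""
    rna = to_rna(sequence)
    total = 0.0
    pairset = set(pairs)
    for i, j in pairset:
        w = PAIR_WEIGHTS.get((rna[i], rna[j]))
        if w is None or j - i - 1 < DEFAULT_MIN_LOOP:
            raise FoldingError(f"illegal pair ({i},{j}) in structure")
        total += w
        if (i + 1, j - 1) in pairset:
            total += STACK_BONUS
    return total
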