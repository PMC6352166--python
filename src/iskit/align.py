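"""Affine-gap local alignment primitives.

This is the numeric core shared by the nucleotide and translated search
stages and by the exhaustive-search oracle.  Alignment is classic
Smith-Waterman with affine gaps: a gap's first base costs ``gap_open``
and each further base ``gap_extend`` (both negative).  Identity is
defined as matches / aligned columns, with gap columns counted as
non-matches and ambiguous bases (N, X) never matching anything,
including themselves.

Multiple alignments per sequence pair are enumerated Waterman-Eggert
style but with subject masking: after each traceback the subject span
of the alignment is replaced by a hard-mismatch sentinel and the matrix
is refilled, so reported alignments never overlap on the subject.
Enumeration stops when the best remaining score drops below
``min_score``.  Tie-break at equal score is the first maximal cell in
row-major order, i.e. smallest query end, then smallest subject end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

NEG_BIG = np.int32(-(10**6))

# sentinel codes: never match; HARD additionally makes any column
# containing them score NEG_BIG so alignments cannot cross them.
AMBIG_CODE = 200  # N / X: plain mismatch, never a match
STOP_CODE = 201   # protein stop '*': hard barrier
MASK_CODE = 202   # masked subject positions: hard barrier

_DNA_MAP = np.full(256, AMBIG_CODE, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _DNA_MAP[ord(_c)] = _i
    _DNA_MAP[ord(_c.lower())] = _i

_PROT_MAP = np.full(256, AMBIG_CODE, dtype=np.uint8)
for _i, _c in enumerate("ACDEFGHIKLMNPQRSTVWYUO"):
    _PROT_MAP[ord(_c)] = _i
_PROT_MAP[ord("*")] = STOP_CODE


def encode_dna(seq: str) -> np.ndarray:
    return _DNA_MAP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_protein(seq: str) -> np.ndarray:
    return _PROT_MAP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    """Alignment scores; gap_open is the cost of a gap's first base."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("match must be positive; penalties negative")


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of query against subject (0-based half-open)."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


@njit(cache=True)
def _fill(q, s, match, mismatch, gap_open, gap_extend):
    n, m = len(q), len(s)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG_BIG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG_BIG, dtype=np.int32)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            sj = s[j - 1]
            if qi >= 201 or sj >= 201:  # stop codon or mask: hard barrier
                sub = NEG_BIG
            elif qi == sj and qi < 200:
                sub = match
            else:
                sub = mismatch
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            if sj >= 201:  # gaps may not consume barrier characters either
                e = NEG_BIG
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            if qi >= 201:
                f = NEG_BIG
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _refill(q, s, H, E, F, match, mismatch, gap_open, gap_extend, j_start, j_min_stop):
    """Recompute columns >= j_start in place after a subject masking.

    Masking only raises penalties inside a subject interval, so its
    effect dies out rightward; once a recomputed column (at or beyond
    the masked interval's end, j_min_stop) is identical to its previous
    values, all further columns are unchanged and the loop stops.
    """
    n, m = len(q), len(s)
    for j in range(j_start, m + 1):
        changed = False
        sj = s[j - 1]
        for i in range(1, n + 1):
            qi = q[i - 1]
            if qi >= 201 or sj >= 201:
                sub = NEG_BIG
            elif qi == sj and qi < 200:
                sub = match
            else:
                sub = mismatch
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            if sj >= 201:
                e = NEG_BIG
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            if qi >= 201:
                f = NEG_BIG
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            if h != H[i, j] or e != E[i, j] or f != F[i, j]:
                changed = True
                H[i, j] = h
                E[i, j] = e
                F[i, j] = f
        if not changed and j >= j_min_stop:
            break


def _traceback(H, E, F, q, s, scoring, i, j) -> LocalAlignment:
    match, mismatch = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    score = int(H[i, j])
    q_end, s_end = i, j
    matches = 0
    columns = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            qi, sj = q[i - 1], s[j - 1]
            if qi >= 201 or sj >= 201:
                sub = NEG_BIG
            elif qi == sj and qi < 200:
                sub = match
            else:
                sub = mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                columns += 1
                if qi == sj and qi < 200:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i, j] == H[i, j - 1] + go:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # F
            columns += 1
            if F[i, j] == H[i - 1, j] + go:
                i -= 1
                state = "H"
            else:
                i -= 1
    return LocalAlignment(i, q_end, j, s_end, score, matches, columns)


def local_align_all(
    q: np.ndarray,
    s: np.ndarray,
    scoring: Scoring,
    min_score: int,
    max_alignments: int = 200,
) -> list[LocalAlignment]:
    """Enumerate subject-disjoint local alignments with score >= min_score.

    Alignments are found best-score first; each one masks its subject
    span before the search continues, so no subject position supports
    two alignments.  ``min_score`` must be positive.
    """
    if min_score <= 0:
        raise ValueError("min_score must be positive")
    if len(q) == 0 or len(s) == 0:
        return []
    s_work = s.copy()
    out: list[LocalAlignment] = []
    H, E, F = _fill(
        q, s_work, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    while len(out) < max_alignments:
        flat = int(np.argmax(H))
        i, j = divmod(flat, H.shape[1])
        if H[i, j] < min_score:
            break
        aln = _traceback(H, E, F, q, s_work, scoring, i, j)
        out.append(aln)
        if aln.s_end <= aln.s_start:  # safety: avoid non-progress
            break
        s_work[aln.s_start : aln.s_end] = MASK_CODE
        _refill(
            q, s_work, H, E, F,
            scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
            aln.s_start + 1, aln.s_end + 1,
        )
    return out


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N mismatches everything."""
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(1 for x, y in zip(a, b) if x != y or x not in "ACGT")
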