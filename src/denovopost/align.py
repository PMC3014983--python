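"""Pairwise alignment primitives used for contig classification and rescue.

Scoring is fixed across the package: match +1, mismatch -1, gap -2 (linear),
with end gaps free in the overlap (semi-global) mode.  Identity is defined as
matches / aligned columns, where gap columns inside the aligned region count
in the denominator and free end-gap overhangs do not.

Determinism: when several alignments are co-optimal the reported identity
depends on which one is traced back.  We pin this down so results are
reproducible: the end cell is the boundary cell maximising (score, i, j), and
the traceback prefers diagonal over up over left moves.  ``overlap_identity``
additionally evaluates the pair in a canonical order (lexicographically
smaller sequence first) so that it is exactly symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -2


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


@njit(cache=True)
def _fill_overlap(a, b):  # pragma: no cover - exercised via python wrappers
    n = a.size
    m = b.size
    H = np.zeros((n + 1, m + 1), np.int32)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = 1 if ai == b[j - 1] else -1
            best = H[i - 1, j - 1] + s
            u = H[i - 1, j] - 2
            if u > best:
                best = u
            l = H[i, j - 1] - 2
            if l > best:
                best = l
            H[i, j] = best
    return H


@njit(cache=True)
def _fill_local(a, b):  # pragma: no cover - exercised via python wrappers
    n = a.size
    m = b.size
    H = np.zeros((n + 1, m + 1), np.int32)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = 1 if ai == b[j - 1] else -1
            best = H[i - 1, j - 1] + s
            u = H[i - 1, j] - 2
            if u > best:
                best = u
            l = H[i, j - 1] - 2
            if l > best:
                best = l
            if best < 0:
                best = 0
            H[i, j] = best
    return H


@dataclass(frozen=True)
class OverlapAlignment:
    """Best overlap alignment of two sequences.

    ``a_aln``/``b_aln`` are the aligned region with ``-`` for gaps; the
    half-open coordinates give the aligned region on each input, so the
    unaligned overhangs are ``a[:a_start]``, ``a[a_end:]`` and likewise for
    ``b``.
    """

    score: int
    matches: int
    columns: int
    a_aln: str
    b_aln: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _best_boundary_cell(H: np.ndarray) -> tuple[int, int]:
    n = H.shape[0] - 1
    m = H.shape[1] - 1
    best = (int(H[n, 0]), n, 0)
    for j in range(m + 1):
        cand = (int(H[n, j]), n, j)
        if cand > best:
            best = cand
    for i in range(n + 1):
        cand = (int(H[i, m]), i, m)
        if cand > best:
            best = cand
    return best[1], best[2]


def overlap_align(a: str, b: str) -> OverlapAlignment:
    """Semi-global (overlap) alignment with free end gaps on both sequences."""
    ea, eb = _encode(a), _encode(b)
    H = _fill_overlap(ea, eb)
    i, j = _best_boundary_cell(H)
    a_end, b_end = i, j
    a_cols: list[str] = []
    b_cols: list[str] = []
    matches = 0
    while i > 0 and j > 0:
        s = MATCH if ea[i - 1] == eb[j - 1] else MISMATCH
        if H[i, j] == H[i - 1, j - 1] + s:
            a_cols.append(a[i - 1])
            b_cols.append(b[j - 1])
            if s == MATCH:
                matches += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP:
            a_cols.append(a[i - 1])
            b_cols.append("-")
            i -= 1
        else:
            a_cols.append("-")
            b_cols.append(b[j - 1])
            j -= 1
    a_cols.reverse()
    b_cols.reverse()
    return OverlapAlignment(
        score=int(H[a_end, b_end]),
        matches=matches,
        columns=len(a_cols),
        a_aln="".join(a_cols),
        b_aln="".join(b_cols),
        a_start=i,
        a_end=a_end,
        b_start=j,
        b_end=b_end,
    )


def overlap_identity(a: str, b: str, min_overlap: int = 40) -> float | None:
    """Identity of the best overlap alignment, or None below ``min_overlap``.

    Symmetric by construction: the pair is evaluated in canonical
    (lexicographic) order.  ``overlap_identity(a, a) == 1.0`` whenever
    ``len(a) >= min_overlap``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if b < a:
        a, b = b, a
    aln = overlap_align(a, b)
    if aln.columns < min_overlap:
        return None
    return aln.identity


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    matches: int
    columns: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def local_align(a: str, b: str) -> LocalAlignment:
    """Smith-Waterman local alignment under the package-wide scoring."""
    ea, eb = _encode(a), _encode(b)
    H = _fill_local(ea, eb)
    flat = int(np.argmax(H))
    # argmax returns the first maximum in row-major order; convert to the
    # (largest i, largest j) convention by scanning equals.
    best_score = int(H.flat[flat])
    ii, jj = np.nonzero(H == best_score)
    i, j = int(ii[-1]), int(jj[-1])
    a_end, b_end = i, j
    matches = 0
    columns = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = MATCH if ea[i - 1] == eb[j - 1] else MISMATCH
        if H[i, j] == H[i - 1, j - 1] + s:
            if s == MATCH:
                matches += 1
            columns += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return LocalAlignment(
        score=best_score,
        matches=matches,
        columns=columns,
        a_start=i,
        a_end=a_end,
        b_start=j,
        b_end=b_end,
    )
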