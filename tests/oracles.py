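"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a quantity along a different code path from the
package (full-matrix pure-python DP, exhaustive hypergeometric enumeration,
boolean transitive closure, literal codon table) so that agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import math
import re

MATCH, MISMATCH, GAP = 1, -1, -2


def overlap_oracle(a: str, b: str) -> tuple[int, int, int]:
    """Full-matrix overlap alignment: (score, matches, columns).

    Uses the same canonical conventions as the package (end cell maximises
    (score, i, j) over the last row and column; traceback prefers diagonal,
    then up, then left) but is an independent plain-python implementation.
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        row, prev = H[i], H[i - 1]
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            row[j] = max(prev[j - 1] + s, prev[j] + GAP, row[j - 1] + GAP)
    cells = [(H[n][j], n, j) for j in range(m + 1)]
    cells += [(H[i][m], i, m) for i in range(n + 1)]
    score, i, j = max(cells)
    matches = columns = 0
    while i > 0 and j > 0:
        s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += int(s == MATCH)
            columns += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + GAP:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return score, matches, columns


def fisher_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = point(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = point(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def components_oracle(nodes: list[str], edges: list[tuple[str, str]]) -> set[frozenset]:
    """Connected components via boolean transitive closure (matrix squaring)."""
    import numpy as np

    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for a, b in edges:
        reach[idx[a], idx[b]] = reach[idx[b], idx[a]] = True
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    comps = set()
    for i in range(n):
        comps.add(frozenset(nodes[j] for j in range(n) if reach[i, j]))
    return comps


def bh_oracle(ps: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up computed by hand."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    qs = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * ps[i] / rank_from_top)
        qs[i] = running
    return qs


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def coding_effect_oracle(position: int, alt: str, orf, seq: str) -> str:
    """Re-translate the affected codon from a literal codon table."""
    idx = position - 1
    if not (orf.start <= idx < orf.end):
        return "noncoding"
    if orf.strand == "+":
        cds = seq[orf.start : orf.end]
        off = idx - orf.start
        alt_b = alt
    else:
        cds = "".join(_COMPLEMENT[c] for c in reversed(seq[orf.start : orf.end]))
        off = orf.end - 1 - idx
        alt_b = _COMPLEMENT[alt]
    ci = off // 3
    codon = cds[ci * 3 : ci * 3 + 3]
    mutant = codon[: off % 3] + alt_b + codon[off % 3 + 1 :]
    same = _CODON_TABLE.get(codon, "X") == _CODON_TABLE.get(mutant, "X")
    return "synonymous" if same else "nonsynonymous"


def is_ts_oracle(ref: str, alt: str) -> bool:
    return {ref, alt} in ({"A", "G"}, {"C", "T"})


def in_homopolymer_oracle(seq: str, position: int, min_run: int = 3) -> bool:
    """Position (1-based) inside or adjacent to a >=min_run homopolymer."""
    for m in re.finditer(r"(A+|C+|G+|T+|N+)", seq):
        if m.end() - m.start() >= min_run:
            if m.start() + 1 - 1 <= position <= m.end() + 1:
                return True
    return False


def filter_oracle(variants, seqs, min_cov=5, max_cov=100, min_prob=0.9, hp_len=3):
    """One-line set-comprehension restatement of the variant filter."""
    return [
        v
        for v in variants
        if min_cov <= v.coverage <= max_cov
        and v.probability >= min_prob
        and not (
            v.var_type in ("INS", "DEL")
            and in_homopolymer_oracle(seqs[v.contig_id], v.position, hp_len)
        )
    ]
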