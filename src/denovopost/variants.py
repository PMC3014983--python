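"""Variant filtering and per-contig selection statistics.

The screen works on raw polymorphism counts, not per-site rates: for every
contig with SNPs the transition/transversion ratio is ``(TS+1)/(TV+1)`` and,
when the contig has a predicted ORF, the nonsynonymous/synonymous ratio is
``(Ka+1)/(Ks+1)``.  The +1 smoothing keeps the ratios defined when either
count is zero.  Contigs in the top percentile of variants per bp are flagged
highly variable, and the intersection ``Ka/Ks > 1`` and ``TS/TV < 1`` and
highly-variable is the diversifying-selection candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from Bio.Seq import Seq

from .records import OrfRecord, SequenceRecord, VariantRecord

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def homopolymer_mask(seq: str, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside or immediately adjacent to a
    homopolymer run of at least ``min_run`` identical bases."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            mask[max(i - 1, 0) : min(j + 1, n)] = True
        i = j
    return mask


def filter_variants(
    variants: list[VariantRecord],
    contig_seqs: dict[str, str],
    min_cov: int = 5,
    max_cov: int = 100,
    min_prob: float = 0.9,
    homopolymer_len: int = 3,
) -> list[VariantRecord]:
    """High-confidence variant filter.

    A call is removed iff coverage < ``min_cov`` OR coverage > ``max_cov`` OR
    probability < ``min_prob`` (strict inequalities: the boundary values 5,
    100 and 0.9 all survive).  INS/DEL calls inside or immediately adjacent
    to a homopolymer run of >= ``homopolymer_len`` identical bases are
    additionally removed.  Idempotent.
    """
    masks: dict[str, np.ndarray] = {}
    out: list[VariantRecord] = []
    for v in variants:
        if v.contig_id not in contig_seqs:
            raise KeyError(f"variant references unknown contig {v.contig_id}")
        if v.coverage < min_cov or v.coverage > max_cov or v.probability < min_prob:
            continue
        if v.is_indel:
            if v.contig_id not in masks:
                masks[v.contig_id] = homopolymer_mask(
                    contig_seqs[v.contig_id], homopolymer_len
                )
            mask = masks[v.contig_id]
            if 0 <= v.position - 1 < mask.size and mask[v.position - 1]:
                continue
        out.append(v)
    return out


def classify_substitution(ref: str, alt: str) -> str:
    """TS (purine<->purine or pyrimidine<->pyrimidine) vs TV (cross-class)."""
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT substitution {ref}->{alt}")
    same_class = (ref in _PURINES) == (alt in _PURINES)
    return "TS" if same_class else "TV"


def coding_effect(snp: VariantRecord, orf: OrfRecord, seq: str) -> str:
    """Classify a SNP against an ORF: synonymous / nonsynonymous / noncoding.

    The containing codon is translated with the reference and the alternate
    base under the standard genetic code (the ORF is reverse-complemented
    first on the minus strand); a stop codon counts as an amino-acid state.
    SNPs are evaluated one at a time against the reference codon.
    """
    if orf.end > len(seq):
        raise ValueError(f"ORF window exceeds contig {snp.contig_id}")
    idx = snp.position - 1
    if not (orf.start <= idx < orf.end):
        return "noncoding"
    if orf.strand == "+":
        cds = seq[orf.start : orf.end]
        off = idx - orf.start
        alt_base = snp.alt_allele
    else:
        cds = str(Seq(seq[orf.start : orf.end]).reverse_complement())
        off = orf.end - 1 - idx
        alt_base = str(Seq(snp.alt_allele).complement())
    codon_i = off // 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    within = off % 3
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def find_longest_orf(sequence: str, min_len: int = 30) -> OrfRecord | None:
    """Longest ATG..stop span (stop included) of at least ``min_len`` nt.

    All six frames are scanned.  Ties prefer the + strand, then the lowest
    frame index, then the smallest start on the scanned strand.
    """
    seq = sequence.upper()
    n = len(seq)
    candidates: list[tuple[int, int, int, int, str]] = []
    for strand_i, (s, strand) in enumerate(
        ((seq, "+"), (str(Seq(seq).reverse_complement()), "-"))
    ):
        for frame in range(3):
            start_atg: int | None = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    if start_atg is not None:
                        length = pos + 3 - start_atg
                        if length >= min_len:
                            candidates.append(
                                (-length, strand_i, frame, start_atg, strand)
                            )
                        start_atg = None
                elif codon == "ATG" and start_atg is None:
                    start_atg = pos
    if not candidates:
        return None
    neg_len, _strand_i, _frame, start, strand = min(candidates)
    length = -neg_len
    if strand == "+":
        return OrfRecord(contig_id="", start=start, end=start + length, strand="+")
    # map back from the reverse complement to forward coordinates
    return OrfRecord(
        contig_id="", start=n - (start + length), end=n - start, strand="-"
    )


@dataclass
class ContigVariantSummary:
    """Per-contig variant counts and smoothed selection ratios."""

    contig_id: str
    length: int
    n_snp: int
    n_indel: int
    ts: int
    tv: int
    ka: int | None
    ks: int | None
    tstv_ratio: float
    kaks_ratio: float | None
    density: float
    density_per_200bp: float
    highly_variable: bool = False

    @property
    def n_variants(self) -> int:
        return self.n_snp + self.n_indel


def summarize_contig(
    contig: SequenceRecord,
    variants: list[VariantRecord],
    orf: OrfRecord | None = None,
) -> ContigVariantSummary:
    """Count TS/TV (all SNPs) and Ka/Ks (SNPs inside the ORF, if any)."""
    ts = tv = 0
    ka = ks = 0
    n_snp = n_indel = 0
    for v in variants:
        if v.contig_id != contig.id:
            raise ValueError(f"variant on {v.contig_id} passed with contig {contig.id}")
        if v.var_type == "SNP":
            n_snp += 1
            if classify_substitution(v.ref_allele, v.alt_allele) == "TS":
                ts += 1
            else:
                tv += 1
            if orf is not None:
                effect = coding_effect(v, orf, contig.residues)
                if effect == "synonymous":
                    ks += 1
                elif effect == "nonsynonymous":
                    ka += 1
        else:
            n_indel += 1
    length = len(contig.residues)
    density = (n_snp + n_indel) / length
    return ContigVariantSummary(
        contig_id=contig.id,
        length=length,
        n_snp=n_snp,
        n_indel=n_indel,
        ts=ts,
        tv=tv,
        ka=ka if orf is not None else None,
        ks=ks if orf is not None else None,
        tstv_ratio=(ts + 1) / (tv + 1),
        kaks_ratio=(ka + 1) / (ks + 1) if orf is not None else None,
        density=density,
        density_per_200bp=density * 200.0,
    )


def flag_highly_variable(
    summaries: list[ContigVariantSummary], q: float = 0.99
) -> list[ContigVariantSummary]:
    """Flag contigs at or above the nearest-rank ``q`` quantile of density.

    The quantile is computed over contigs with at least one variant, with
    rank ``floor(q*n) + 1`` (so 100 distinct densities at q=0.99 flag exactly
    the maximum).  Sets ``highly_variable`` in place and returns the flagged
    subset.
    """
    with_var = [s for s in summaries if s.n_variants >= 1]
    if not with_var:
        raise ValueError("no contig has a variant")
    densities = sorted(s.density for s in with_var)
    n = len(densities)
    rank = min(int(np.floor(q * n)) + 1, n)
    threshold = densities[rank - 1]
    flagged = []
    for s in summaries:
        s.highly_variable = s.n_variants >= 1 and s.density >= threshold
        if s.highly_variable:
            flagged.append(s)
    return flagged


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    f_stat: float
    df: int
    p_value: float


def regress_variants_on_length(
    summaries: list[ContigVariantSummary],
) -> RegressionResult:
    """OLS of variant count on contig length over contigs with >=1 variant."""
    pts = [(s.length, s.n_variants) for s in summaries if s.n_variants >= 1]
    if len(pts) < 3:
        raise ValueError("need at least 3 contigs with variants")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("degenerate regression: all contig lengths equal")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        f_stat=float(model.fvalue),
        df=int(model.df_resid),
        p_value=float(model.f_pvalue),
    )


def selection_candidates(
    summaries: list[ContigVariantSummary],
) -> list[ContigVariantSummary]:
    """Contigs with Ka/Ks > 1 AND TS/TV < 1 AND flagged highly variable."""
    return [
        s
        for s in summaries
        if s.kaks_ratio is not None
        and s.kaks_ratio > 1
        and s.tstv_ratio < 1
        and s.highly_variable
    ]
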