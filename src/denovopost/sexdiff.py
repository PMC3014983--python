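"""Sex-of-origin classification and sex-specific gene calling.

Reads come from two sex-pooled normalized libraries, so each contig can be
classified by the sexes of the reads placed on it: FC (female reads only),
MC (male only) or BC (both).  Because the libraries are normalized, the
calling is presence/absence, not quantitative: a gene (homology accession)
is female-specific when it is hit by female-only sequence at a strict
e-value cut-off and by no male-side sequence even at the loose screening
cut-off; symmetric for males.  BC contigs contain reads of both sexes and
therefore disqualify specificity on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import BlastHit, GoAnnotation, ReadStatusRecord

FEMALE_CLASSES = ("FC", "F")
MALE_CLASSES = ("MC", "M")


def classify_sequences(
    records: list[ReadStatusRecord],
    contigs: list[str] | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Classify contigs (FC/MC/BC) and singletons (F/M) by read sex.

    A split read contributes its sex to both linked contigs.  If ``contigs``
    is given, any listed contig without a placed read raises (it cannot be
    classified).
    """
    sexes: dict[str, set[str]] = {}
    singleton_classes: dict[str, str] = {}
    for rec in records:
        if rec.status == "singleton":
            singleton_classes[rec.read_id] = rec.sex
        for p in rec.placements:
            sexes.setdefault(p.contig_id, set()).add(rec.sex)
    contig_classes = {
        cid: ("BC" if len(s) == 2 else ("FC" if "F" in s else "MC"))
        for cid, s in sexes.items()
    }
    if contigs is not None:
        missing = sorted(set(contigs) - set(contig_classes))
        if missing:
            raise ValueError(f"contigs without placed reads: {missing[:5]}")
    return contig_classes, singleton_classes


@dataclass(frozen=True)
class GeneEvidence:
    """Per-accession sex evidence: which sequences hit it, at what e-values."""

    subject_id: str
    call: str  # female_specific | male_specific | shared | insufficient
    female_seqs: frozenset[str]
    male_seqs: frozenset[str]
    best_female_evalue: float | None
    best_male_evalue: float | None


def call_sex_specific(
    hits: list[BlastHit],
    classes: dict[str, str],
    strict_cutoff: float = 1e-50,
    screen_cutoff: float = 1e-5,
) -> dict[str, GeneEvidence]:
    """Call each hit accession female/male-specific, shared or insufficient.

    Female-specific: at least one FC contig or F singleton hits the
    accession at e <= ``strict_cutoff`` AND no MC/BC contig or M singleton
    hits it at e <= ``screen_cutoff`` (the conservative reading of screening
    "down to" the strict cut-off across the whole e-value ladder).
    Symmetric for males.  Shared: qualifying (screen-level) evidence from
    both sides.  Insufficient otherwise.
    """
    by_subject: dict[str, list[BlastHit]] = {}
    for h in hits:
        if h.query_id in classes:
            by_subject.setdefault(h.subject_id, []).append(h)
    out: dict[str, GeneEvidence] = {}
    for subject in sorted(by_subject):
        f_strict = m_strict = False
        f_any = m_any = False
        female_seqs: set[str] = set()
        male_seqs: set[str] = set()
        best_f: float | None = None
        best_m: float | None = None
        for h in by_subject[subject]:
            cls = classes[h.query_id]
            if h.evalue > screen_cutoff:
                continue
            female_side = cls in FEMALE_CLASSES or cls == "BC"
            male_side = cls in MALE_CLASSES or cls == "BC"
            if female_side:
                f_any = True
                female_seqs.add(h.query_id)
                best_f = h.evalue if best_f is None else min(best_f, h.evalue)
                if cls in FEMALE_CLASSES and h.evalue <= strict_cutoff:
                    f_strict = True
            if male_side:
                m_any = True
                male_seqs.add(h.query_id)
                best_m = h.evalue if best_m is None else min(best_m, h.evalue)
                if cls in MALE_CLASSES and h.evalue <= strict_cutoff:
                    m_strict = True
        if f_strict and not m_any:
            call = "female_specific"
        elif m_strict and not f_any:
            call = "male_specific"
        elif f_any and m_any:
            call = "shared"
        else:
            call = "insufficient"
        out[subject] = GeneEvidence(
            subject_id=subject,
            call=call,
            female_seqs=frozenset(female_seqs),
            male_seqs=frozenset(male_seqs),
            best_female_evalue=best_f,
            best_male_evalue=best_m,
        )
    return out


def fisher_exact(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value for a 2x2 count table.

    Two-sided by the point-probability rule: sum the hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed that of the observed table.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be a non-negative 2x2 count table")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(arr, alternative=alternative)[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    q_value: float


def go_enrichment(
    set_a: set[str],
    set_b: set[str],
    annotations: list[GoAnnotation],
    alternative: str = "two-sided",
) -> list[EnrichmentResult]:
    """Fisher's exact enrichment of GO terms between two gene sets.

    One test per term annotated to at least one gene of either set, on the
    table (has term / lacks term) x (set A / set B), BH-corrected across
    terms.  Results sorted by q then p then term id.
    """
    terms_of: dict[str, set[str]] = {}
    for ann in annotations:
        terms_of.setdefault(ann.seq_id, set()).add(ann.term_id)
    tested_terms = sorted(
        {t for g in (set_a | set_b) for t in terms_of.get(g, set())}
    )
    if not tested_terms:
        return []
    rows = []
    for term in tested_terms:
        a_t = sum(1 for g in set_a if term in terms_of.get(g, set()))
        b_t = sum(1 for g in set_b if term in terms_of.get(g, set()))
        table = ((a_t, len(set_a) - a_t), (b_t, len(set_b) - b_t))
        rows.append((term, table, fisher_exact(table, alternative)))
    qs = bh_fdr([r[2] for r in rows])
    results = [
        EnrichmentResult(term_id=t, table=tab, p_value=p, q_value=float(q))
        for (t, tab, p), q in zip(rows, qs)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term_id))
    return results


def subsample_reads(
    records: list[ReadStatusRecord], fraction: float, seed: int = 0
) -> list[ReadStatusRecord]:
    """Keep a nested random subset of reads.

    Each read gets one uniform draw (from ``seed``, in sorted read-id order)
    and is kept when the draw is below ``fraction`` — so the subset at a
    lower fraction is contained in the subset at a higher one, which makes
    depth-grid comparisons monotone by construction.
    """
    ids = sorted(r.read_id for r in records)
    rng = np.random.default_rng(seed)
    u = dict(zip(ids, rng.random(len(ids))))
    return [r for r in records if u[r.read_id] < fraction]
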