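"""Homology clustering, unique-homolog counting, chimera detection and
singleton rescue.

These operations consume tabular homology evidence (BLAST-style hits against
one or more reference databases) — running the searches themselves is out of
scope.  Homology clustering groups contigs and singletons that share a best
subject accession at an e-value cut-off; the per-database presence sets feed
a Venn summary; chimeric contigs show two strong hits to different genes at
opposite ends of the query; and singletons that align almost end-to-end to a
contig at high identity are rescued as redundant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .align import local_align
from .records import BlastHit, SequenceRecord

DEFAULT_CUTOFFS = (1e-5, 1e-10, 1e-20, 1e-50)


@dataclass(frozen=True)
class HomologyCluster:
    db_name: str
    subject_id: str
    members: frozenset[str]
    cutoff: float


def cluster_by_homolog(
    hits: list[BlastHit], db_name: str, cutoff: float
) -> tuple[list[HomologyCluster], dict[str, list[str]]]:
    """Group sequences by shared subject accession at an e-value cut-off.

    A sequence joins every cluster it hits; sequences in two or more
    clusters are reported separately in the multi-membership map.
    """
    members: dict[str, set[str]] = {}
    for h in hits:
        if h.db_name == db_name and h.evalue <= cutoff:
            members.setdefault(h.subject_id, set()).add(h.query_id)
    clusters = [
        HomologyCluster(
            db_name=db_name,
            subject_id=subject,
            members=frozenset(members[subject]),
            cutoff=cutoff,
        )
        for subject in sorted(members)
    ]
    n_clusters_of: dict[str, list[str]] = {}
    for c in clusters:
        for seq in c.members:
            n_clusters_of.setdefault(seq, []).append(c.subject_id)
    multi = {
        seq: sorted(subjects)
        for seq, subjects in sorted(n_clusters_of.items())
        if len(subjects) >= 2
    }
    return clusters, multi


def unique_homolog_counts(
    hits: list[BlastHit], cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
) -> pd.DataFrame:
    """Distinct subject accessions with >=1 qualifying hit, per db per cut-off.

    Counts are monotone non-increasing as the cut-off tightens (qualifying
    hit sets are nested).
    """
    dbs = sorted({h.db_name for h in hits})
    data = {}
    for cutoff in cutoffs:
        col = []
        for db in dbs:
            col.append(
                len({h.subject_id for h in hits if h.db_name == db and h.evalue <= cutoff})
            )
        data[cutoff] = col
    return pd.DataFrame(data, index=dbs)


def presence_venn(
    hits: list[BlastHit], db_list: list[str], cutoff: float
) -> tuple[dict[str, frozenset[str]], dict[frozenset[str], int]]:
    """Per-sequence database presence sets and Venn region counts.

    Returns, for each sequence with >=1 qualifying hit, the subset of
    databases it was found in, and the aggregated count per subset.  The
    regions partition the annotated sequences.
    """
    presence: dict[str, set[str]] = {}
    wanted = set(db_list)
    for h in hits:
        if h.db_name in wanted and h.evalue <= cutoff:
            presence.setdefault(h.query_id, set()).add(h.db_name)
    per_seq = {seq: frozenset(dbs) for seq, dbs in presence.items()}
    regions: dict[frozenset[str], int] = {}
    for dbs in per_seq.values():
        regions[dbs] = regions.get(dbs, 0) + 1
    return per_seq, regions


@dataclass(frozen=True)
class ChimeraCall:
    seq_id: str
    hit_a: BlastHit
    hit_b: BlastHit
    query_gap: int
    reason: str


def detect_chimeras(
    hits: list[BlastHit],
    max_overlap_frac: float = 0.2,
    evalue_cutoff: float = 1e-20,
    query_lengths: dict[str, int] | None = None,
    whitelist: set[frozenset[str]] | None = None,
) -> list[ChimeraCall]:
    """Flag sequences with two strong hits to different genes at opposite ends.

    A call requires two hits with e < ``evalue_cutoff`` to different subject
    accessions whose query intervals overlap by at most ``max_overlap_frac``
    of the shorter interval and whose midpoints fall in opposite halves of
    the query.  ``whitelist`` holds subject-id pairs known to be co-transcribed
    (e.g. adjacent mitochondrial genes) whose calls are suppressed.  One call
    per sequence, the pair with the smallest combined e-value.
    """
    whitelist = whitelist or set()
    by_query: dict[str, dict[str, BlastHit]] = {}
    for h in hits:
        if h.evalue >= evalue_cutoff:
            continue
        best = by_query.setdefault(h.query_id, {})
        prev = best.get(h.subject_id)
        if prev is None or (h.evalue, -h.bitscore) < (prev.evalue, -prev.bitscore):
            best[h.subject_id] = h
    calls: list[ChimeraCall] = []
    for query in sorted(by_query):
        best = by_query[query]
        if len(best) < 2:
            continue
        if query_lengths and query in query_lengths:
            qlen = query_lengths[query]
        else:
            qlen = max(h.query_end for h in best.values())
        half = qlen / 2.0
        candidates = []
        for sa, sb in combinations(sorted(best), 2):
            if frozenset((sa, sb)) in whitelist:
                continue
            ha, hb = best[sa], best[sb]
            if ha.query_start > hb.query_start:
                ha, hb = hb, ha
            len_a = ha.query_end - ha.query_start + 1
            len_b = hb.query_end - hb.query_start + 1
            overlap = max(
                0, min(ha.query_end, hb.query_end) - hb.query_start + 1
            )
            if overlap > max_overlap_frac * min(len_a, len_b):
                continue
            mid_a = (ha.query_start + ha.query_end) / 2.0
            mid_b = (hb.query_start + hb.query_end) / 2.0
            if not (mid_a < half and mid_b > half):
                continue
            gap = max(hb.query_start - ha.query_end - 1, 0)
            candidates.append((ha.evalue + hb.evalue, ha, hb, gap))
        if candidates:
            _, ha, hb, gap = min(candidates, key=lambda c: (c[0], c[1].subject_id))
            calls.append(
                ChimeraCall(
                    seq_id=query,
                    hit_a=ha,
                    hit_b=hb,
                    query_gap=gap,
                    reason=(
                        f"hits {ha.subject_id} ({ha.evalue:.2g}) and "
                        f"{hb.subject_id} ({hb.evalue:.2g}) on opposite ends"
                    ),
                )
            )
    return calls


@dataclass(frozen=True)
class SingletonMapping:
    read_id: str
    contig_id: str
    identity: float  # percent over aligned columns
    unaligned_5p: int
    unaligned_3p: int


def _kmer_index(contigs: list[SequenceRecord], k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for c in contigs:
        seq = c.residues
        for i in range(0, len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(c.id)
    return index


def map_singletons(
    singletons: list[SequenceRecord],
    contigs: list[SequenceRecord],
    min_identity: float = 95.0,
    max_end_unaligned: int = 10,
    k: int = 20,
) -> list[SingletonMapping]:
    """Rescue singletons that align nearly end-to-end to a contig.

    Candidate contigs are found by shared k-mers (seed-and-extend), then each
    candidate is aligned locally under the package-wide scoring.  A mapping
    is emitted iff identity >= ``min_identity`` percent over the aligned
    columns (gap columns count against identity) and fewer than
    ``max_end_unaligned`` singleton bases are unaligned at each end.  At most
    one mapping per singleton: best identity, then longer aligned span, then
    lexicographically smallest contig id.
    """
    index = _kmer_index(contigs, k)
    contig_seq = {c.id: c.residues for c in contigs}
    mappings: list[SingletonMapping] = []
    for s in singletons:
        seq = s.residues
        if len(seq) < k:
            continue
        candidates: set[str] = set()
        positions = list(range(0, len(seq) - k + 1, max(k // 2, 1)))
        if positions and positions[-1] != len(seq) - k:
            positions.append(len(seq) - k)
        for i in positions:
            candidates |= index.get(seq[i : i + k], set())
        best: tuple[float, int, str, SingletonMapping] | None = None
        for cid in sorted(candidates):
            aln = local_align(seq, contig_seq[cid])
            identity = 100.0 * aln.matches / aln.columns if aln.columns else 0.0
            un5 = aln.a_start
            un3 = len(seq) - aln.a_end
            if identity < min_identity or un5 >= max_end_unaligned or un3 >= max_end_unaligned:
                continue
            key = (-identity, -aln.columns, cid)
            if best is None or key < best[0:3]:
                best = (
                    -identity,
                    -aln.columns,
                    cid,
                    SingletonMapping(
                        read_id=s.id,
                        contig_id=cid,
                        identity=identity,
                        unaligned_5p=un5,
                        unaligned_3p=un3,
                    ),
                )
        if best is not None:
            mappings.append(best[3])
    return mappings
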