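"""Split-read contig graphs: clustering and component classification.

Contigs are nodes; a read the assembler split between two contigs is an
edge.  Connected components of this graph ("graph-clusters") group contigs
that arose from one gene or gene family, and nucleotide similarity between
the member contigs separates the interpretations:

* identity >= 0.95  -> divergent alleles of one gene (merged into a consensus);
* 0.80 <= identity < 0.95 -> the diverged regions of a duplicated gene pair;
* lower or undefined identity -> alternatively spliced exons (or
  non-overlapping pieces) connected only through the split-read topology.

Similarity is evaluated between *all* members of a cluster, not only along
edges: the split-read topology places the two divergent variant contigs as
siblings of a shared-exon hub, so the informative pair is usually not itself
an edge.  Thresholds use closed-left bands (identity exactly 0.95 counts as
allele, exactly 0.80 as duplicate) for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .align import overlap_align, overlap_identity
from .records import BlastHit, ReadStatusRecord, SequenceRecord

_IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
_IUPAC_SETS = {v: k for k, v in _IUPAC.items()}
_IUPAC_SETS["N"] = frozenset("ACGT")


def build_graph(
    records: list[ReadStatusRecord], min_edge_support: int = 1
) -> nx.Graph:
    """Build the contig graph from split-read evidence.

    One edge per unordered contig pair with at least one supporting split
    read; the edge weight is the number of such reads.  Edges with fewer than
    ``min_edge_support`` reads are dropped, and nodes without a surviving
    edge are excluded.
    """
    g = nx.Graph()
    for rec in records:
        if rec.is_split:
            a, b = sorted(p.contig_id for p in rec.placements)
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    drop = [
        (a, b) for a, b, w in g.edges(data="weight") if w < min_edge_support
    ]
    g.remove_edges_from(drop)
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


@dataclass(frozen=True)
class GraphCluster:
    """A connected component of the contig graph."""

    cluster_id: str
    members: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]

    def __len__(self) -> int:
        return len(self.members)


def find_clusters(graph: nx.Graph) -> list[GraphCluster]:
    """Connected components, sorted by descending size then smallest member."""
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda members: (-len(members), members[0]),
    )
    clusters = []
    for i, members in enumerate(comps, start=1):
        sub = graph.subgraph(members)
        edges = tuple(
            sorted(
                (min(a, b), max(a, b), int(w))
                for a, b, w in sub.edges(data="weight", default=1)
            )
        )
        clusters.append(
            GraphCluster(
                cluster_id=f"cluster{i:05d}", members=tuple(members), edges=edges
            )
        )
    return clusters


@dataclass(frozen=True)
class EdgeLabel:
    value: str  # allele | duplicate | splice
    identity: float | None


def label_pair(
    seq_a: str,
    seq_b: str,
    allele_id: float = 0.95,
    dup_id_low: float = 0.80,
    min_overlap: int = 40,
) -> EdgeLabel:
    """Classify a contig pair by overlap identity (splice if undefined)."""
    identity = overlap_identity(seq_a, seq_b, min_overlap=min_overlap)
    if identity is None:
        return EdgeLabel(value="splice", identity=None)
    if identity >= allele_id:
        return EdgeLabel(value="allele", identity=identity)
    if identity >= dup_id_low:
        return EdgeLabel(value="duplicate", identity=identity)
    return EdgeLabel(value="splice", identity=identity)


# kept as the edge-level entry point: an edge is just a member pair
label_edge = label_pair


def consensus_pair(a: str, b: str) -> str:
    """Column-wise consensus of the best overlap alignment of two sequences.

    Equal columns keep the base; substitution columns get the IUPAC
    ambiguity code for the union of the two bases (a tie has no majority);
    gap columns keep the present base.  Free end-gap overhangs are appended
    unchanged, so the consensus spans the union of both sequences.
    """
    aln = overlap_align(a, b)
    head = a[: aln.a_start] + b[: aln.b_start]
    tail = a[aln.a_end :] + b[aln.b_end :]
    cols = []
    for ca, cb in zip(aln.a_aln, aln.b_aln):
        if ca == cb:
            cols.append(ca)
        elif ca == "-":
            cols.append(cb)
        elif cb == "-":
            cols.append(ca)
        else:
            merged = _IUPAC_SETS.get(ca, frozenset(ca)) | _IUPAC_SETS.get(
                cb, frozenset(cb)
            )
            cols.append(_IUPAC[frozenset(merged)])
    return head + "".join(cols) + tail


@dataclass(frozen=True)
class ComponentCall:
    """One interpreted substructure within a graph-cluster."""

    component_id: str
    ctype: str  # merged_alleles | duplicate_pair | alt_splice | unresolved
    members: tuple[str, ...]  # original contig ids
    nodes: tuple[str, ...]  # node ids after allele contraction
    consensus: SequenceRecord | None = None
    identity: float | None = None


@dataclass
class ClusterAnalysis:
    cluster_id: str
    calls: list[ComponentCall]
    contracted_nodes: tuple[str, ...]
    node_members: dict[str, tuple[str, ...]]
    consensus: dict[str, str]


def merge_alleles(
    cluster: GraphCluster,
    sequences: dict[str, str],
    allele_id: float = 0.95,
    dup_id_low: float = 0.80,
    min_overlap: int = 40,
) -> tuple[nx.Graph, list[ComponentCall], dict[str, tuple[str, ...]], dict[str, str]]:
    """Contract allele-labelled member pairs into consensus super-nodes.

    Returns the contracted graph (weights of parallel edges summed), the
    merged_alleles calls, the node->original-members map, and the consensus
    sequences of the super-nodes.
    """
    labels: dict[tuple[str, str], EdgeLabel] = {}
    for a, b in combinations(cluster.members, 2):
        labels[(a, b)] = label_pair(
            sequences[a], sequences[b], allele_id, dup_id_low, min_overlap
        )
    allele_graph = nx.Graph()
    allele_graph.add_nodes_from(cluster.members)
    for (a, b), lab in labels.items():
        if lab.value == "allele":
            allele_graph.add_edge(a, b, identity=lab.identity)

    mapping: dict[str, str] = {}
    node_members: dict[str, tuple[str, ...]] = {}
    consensus: dict[str, str] = {}
    calls: list[ComponentCall] = []
    k = 0
    for group in sorted(nx.connected_components(allele_graph), key=min):
        group = sorted(group)
        if len(group) == 1:
            mapping[group[0]] = group[0]
            node_members[group[0]] = (group[0],)
            continue
        k += 1
        super_id = f"{cluster.cluster_id}_m{k}"
        cons = sequences[group[0]]
        for member in group[1:]:
            cons = consensus_pair(cons, sequences[member])
        for member in group:
            mapping[member] = super_id
        node_members[super_id] = tuple(group)
        consensus[super_id] = cons
        identities = [
            allele_graph[a][b]["identity"]
            for a, b in allele_graph.subgraph(group).edges()
        ]
        calls.append(
            ComponentCall(
                component_id=super_id,
                ctype="merged_alleles",
                members=tuple(group),
                nodes=(super_id,),
                consensus=SequenceRecord(id=super_id, residues=cons),
                identity=min(identities) if identities else None,
            )
        )

    contracted = nx.Graph()
    contracted.add_nodes_from(mapping[m] for m in cluster.members)
    for a, b, w in cluster.edges:
        na, nb = mapping[a], mapping[b]
        if na == nb:
            continue
        if contracted.has_edge(na, nb):
            contracted[na][nb]["weight"] += w
        else:
            contracted.add_edge(na, nb, weight=w)
    return contracted, calls, node_members, consensus


def call_components(
    cluster: GraphCluster,
    sequences: dict[str, str],
    allele_id: float = 0.95,
    dup_id_low: float = 0.80,
    min_overlap: int = 40,
) -> ClusterAnalysis:
    """Full decomposition of one graph-cluster.

    Order of operations: contract allele pairs into merged consensus nodes;
    every duplicate-labelled node pair yields a duplicate_pair call; after
    setting duplicate-pair nodes aside, each residual connected subgraph of
    >= 2 nodes joined by splice edges yields an alt_splice call.  A splice
    subgraph that shares nodes with a duplicate pair is flagged unresolved.
    """
    contracted, calls, node_members, consensus = merge_alleles(
        cluster, sequences, allele_id, dup_id_low, min_overlap
    )
    seq_of = dict(sequences)
    seq_of.update(consensus)

    nodes = sorted(contracted.nodes)
    pair_label: dict[tuple[str, str], EdgeLabel] = {}
    for a, b in combinations(nodes, 2):
        pair_label[(a, b)] = label_pair(
            seq_of[a], seq_of[b], allele_id, dup_id_low, min_overlap
        )

    dup_nodes: set[str] = set()
    k = 0
    for (a, b), lab in sorted(pair_label.items()):
        if lab.value == "duplicate":
            k += 1
            members = tuple(sorted(node_members[a] + node_members[b]))
            calls.append(
                ComponentCall(
                    component_id=f"{cluster.cluster_id}_d{k}",
                    ctype="duplicate_pair",
                    members=members,
                    nodes=(a, b),
                    identity=lab.identity,
                )
            )
            dup_nodes.update((a, b))

    splice_graph = nx.Graph()
    splice_graph.add_nodes_from(nodes)
    for a, b in contracted.edges():
        key = (min(a, b), max(a, b))
        if pair_label[key].value == "splice":
            splice_graph.add_edge(*key)
    splice_graph.remove_nodes_from(list(nx.isolates(splice_graph)))
    k = 0
    for group in sorted(nx.connected_components(splice_graph), key=min):
        group = sorted(group)
        if len(group) < 2:
            continue
        k += 1
        members = tuple(sorted(m for n in group for m in node_members[n]))
        ctype = "unresolved" if dup_nodes & set(group) else "alt_splice"
        calls.append(
            ComponentCall(
                component_id=f"{cluster.cluster_id}_s{k}",
                ctype=ctype,
                members=members,
                nodes=tuple(group),
            )
        )
    return ClusterAnalysis(
        cluster_id=cluster.cluster_id,
        calls=calls,
        contracted_nodes=tuple(nodes),
        node_members=node_members,
        consensus=consensus,
    )


def blast_category(
    members: tuple[str, ...] | list[str], hits: list[BlastHit]
) -> int:
    """Five-way homology summary of a component.

    ``hits`` must already be restricted to one database at the chosen
    e-value cut-off; "same file" means the same subject accession.
    1: no member has a hit; 2: some members hit, different subjects;
    3: some members hit, all one subject; 4: all members hit, different
    subjects; 5: all members hit, all one subject.
    """
    subjects_by_member = {m: set() for m in members}
    for h in hits:
        if h.query_id in subjects_by_member:
            subjects_by_member[h.query_id].add(h.subject_id)
    with_hit = [m for m in members if subjects_by_member[m]]
    if not with_hit:
        return 1
    all_subjects = set().union(*(subjects_by_member[m] for m in with_hit))
    if len(with_hit) == len(list(members)):
        return 5 if len(all_subjects) == 1 else 4
    return 3 if len(all_subjects) == 1 else 2
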