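"""Contig-graph construction, clustering and component classification."""

import random

import networkx as nx
import pytest

from denovopost import (
    GraphCluster,
    ReadPlacement,
    ReadStatusRecord,
    blast_category,
    build_graph,
    call_components,
    consensus_pair,
    find_clusters,
    label_pair,
    merge_alleles,
    mutate_sequence,
)
from denovopost.records import BlastHit

from oracles import components_oracle


def _split(read_id, a, b, sex="F"):
    return ReadStatusRecord(
        read_id=read_id,
        sex=sex,
        status="partially_assembled",
        placements=(
            ReadPlacement(contig_id=a, read_start=1, read_end=100, contig_start=1),
            ReadPlacement(contig_id=b, read_start=101, read_end=200, contig_start=1),
        ),
    )


def _single(read_id, contig, sex="F"):
    return ReadStatusRecord(
        read_id=read_id,
        sex=sex,
        status="assembled",
        placements=(
            ReadPlacement(contig_id=contig, read_start=1, read_end=200, contig_start=1),
        ),
    )


def test_build_graph_edges_and_weights():
    g = build_graph([_split("r1", "c1", "c2"), _split("r2", "c2", "c3")])
    assert set(g.edges()) == {("c1", "c2"), ("c2", "c3")}
    g3 = build_graph([_split(f"r{i}", "c1", "c2") for i in range(3)])
    assert g3["c1"]["c2"]["weight"] == 3


def test_build_graph_min_support_and_isolates():
    reads = [_split("r1", "c1", "c2"), _split("r2", "c1", "c2"), _split("r3", "c3", "c4")]
    g = build_graph(reads, min_edge_support=2)
    assert set(g.nodes()) == {"c1", "c2"}


def test_single_placement_reads_build_empty_graph():
    g = build_graph([_single("r1", "c1"), _single("r2", "c2")])
    assert g.number_of_nodes() == 0


def test_find_clusters_partition_and_sorting():
    reads = [_split("r1", "c1", "c2"), _split("r2", "c2", "c3"), _split("r3", "c8", "c9")]
    clusters = find_clusters(build_graph(reads))
    assert [c.members for c in clusters] == [("c1", "c2", "c3"), ("c8", "c9")]


def test_find_clusters_match_transitive_closure_oracle():
    rng = random.Random(77)
    nodes = [f"n{i:03d}" for i in range(500)]
    edges = set()
    while len(edges) < 420:
        a, b = rng.sample(nodes, 2)
        edges.add((min(a, b), max(a, b)))
    g = nx.Graph()
    g.add_edges_from(edges)
    clusters = find_clusters(g)
    got = {frozenset(c.members) for c in clusters}
    oracle = {
        c for c in components_oracle(sorted(g.nodes()), sorted(edges)) if len(c) >= 2
    }
    assert got == oracle
    # members partition the non-isolated nodes
    seen = [m for c in clusters for m in c.members]
    assert len(seen) == len(set(seen)) == g.number_of_nodes()


@pytest.mark.parametrize(
    "n_sub,expected",
    [(4, "allele"), (5, "allele"), (13, "duplicate"), (20, "duplicate"), (30, "splice")],
)
def test_label_pair_thresholds(n_sub, expected):
    rng = random.Random(n_sub)
    seq = "".join(rng.choice("ACGT") for _ in range(100))
    other = list(seq)
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for pos in rng.sample(range(100), n_sub):
        other[pos] = swap[other[pos]]
    # transversion swaps keep the optimum on the diagonal, identity = 1 - n/100
    lab = label_pair(seq, "".join(other))
    assert lab.value == expected


def test_label_pair_boundary_semantics():
    # closed-left bands: identity exactly 0.95 -> allele, exactly 0.80 -> duplicate
    rng = random.Random(19)
    base = "".join(rng.choice("ACGT") for _ in range(100))
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}

    def mutate_at(positions):
        out = list(base)
        for p in positions:
            out[p] = swap[out[p]]
        return "".join(out)

    # evenly spread transversions keep the optimal alignment on the diagonal
    at95 = label_pair(base, mutate_at(range(10, 100, 20)))  # 5 substitutions
    assert (at95.value, at95.identity) == ("allele", 0.95)
    at80 = label_pair(base, mutate_at(range(2, 100, 5)))  # 20 substitutions
    assert (at80.value, at80.identity) == ("duplicate", 0.80)


def test_label_pair_disjoint_sequences_is_splice():
    rng = random.Random(123)
    a = "".join(rng.choice("ACGT") for _ in range(200))
    b = "".join(rng.choice("ACGT") for _ in range(200))
    assert label_pair(a, b).value == "splice"


def test_consensus_iupac_tie():
    assert consensus_pair("ACGT" * 20 + "ACGT", "ACGT" * 20 + "ACTT") \
        == "ACGT" * 20 + "AC" + "K" + "T"


def test_merge_alleles_pair_cluster():
    rng = random.Random(31)
    a = "".join(rng.choice("ACGT") for _ in range(500))
    b = mutate_sequence(a, 0.03, seed=1)
    cluster = GraphCluster("cl1", members=("c1", "c2"), edges=(("c1", "c2", 3),))
    contracted, calls, node_members, consensus = merge_alleles(
        cluster, {"c1": a, "c2": b}
    )
    assert len(calls) == 1 and calls[0].ctype == "merged_alleles"
    assert calls[0].members == ("c1", "c2")
    assert contracted.number_of_nodes() == 1
    assert len(consensus) == 1


def test_merge_alleles_no_allele_edges_unchanged():
    rng = random.Random(32)
    seqs = {
        "c1": "".join(rng.choice("ACGT") for _ in range(300)),
        "c2": "".join(rng.choice("ACGT") for _ in range(300)),
    }
    cluster = GraphCluster("cl1", members=("c1", "c2"), edges=(("c1", "c2", 1),))
    contracted, calls, _, _ = merge_alleles(cluster, seqs)
    assert calls == [] and set(contracted.nodes()) == {"c1", "c2"}


def test_call_components_duplicate_pair():
    rng = random.Random(33)
    shared = "".join(rng.choice("ACGT") for _ in range(400))
    a = "".join(rng.choice("ACGT") for _ in range(400))
    b = mutate_sequence(a, 0.12, seed=2)  # identity ~0.88
    cluster = GraphCluster(
        "cl1", members=("c1", "c2", "c3"),
        edges=(("c1", "c2", 2), ("c1", "c3", 2)),
    )
    analysis = call_components(cluster, {"c1": shared, "c2": a, "c3": b})
    dups = [c for c in analysis.calls if c.ctype == "duplicate_pair"]
    assert len(dups) == 1 and dups[0].members == ("c2", "c3")


def test_call_components_alt_splice_triangle():
    rng = random.Random(34)
    seqs = {f"e{i}": "".join(rng.choice("ACGT") for _ in range(400)) for i in range(3)}
    cluster = GraphCluster(
        "cl1", members=("e0", "e1", "e2"),
        edges=(("e0", "e1", 1), ("e0", "e2", 1), ("e1", "e2", 1)),
    )
    analysis = call_components(cluster, seqs)
    alts = [c for c in analysis.calls if c.ctype == "alt_splice"]
    assert len(alts) == 1 and alts[0].members == ("e0", "e1", "e2")


def test_contig_conservation_across_calls(small_dataset):
    from denovopost import build_graph, find_clusters

    seqs = {c.id: c.residues for c in small_dataset.contigs}
    clusters = find_clusters(build_graph(small_dataset.read_status))
    for cluster in clusters:
        analysis = call_components(cluster, seqs)
        in_calls = {m for call in analysis.calls for m in call.members}
        assert in_calls <= set(cluster.members)
        contracted_total = {
            m for n in analysis.contracted_nodes for m in analysis.node_members[n]
        }
        assert contracted_total == set(cluster.members)


@pytest.mark.parametrize(
    "hit_map,expected",
    [
        ({}, 1),
        ({"c1": {"X"}, "c2": {"Y"}, "c3": set()}, 2),
        ({"c1": {"X"}, "c2": {"X"}, "c3": set()}, 3),
        ({"c1": {"X"}, "c2": {"Y"}, "c3": {"X"}}, 4),
        ({"c1": {"X"}, "c2": {"X"}, "c3": {"X"}}, 5),
    ],
)
def test_blast_category_five_way(hit_map, expected):
    members = ("c1", "c2", "c3")
    hits = [
        BlastHit(
            query_id=q, db_name="NR", subject_id=s, percent_identity=90.0,
            align_length=100, mismatches=0, gap_opens=0, query_start=1,
            query_end=100, subject_start=1, subject_end=33, evalue=1e-30,
            bitscore=100.0,
        )
        for q, subjects in hit_map.items()
        for s in subjects
    ]
    assert blast_category(members, hits) == expected
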