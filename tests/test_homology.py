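"""Homology clustering, unique-homolog counts, chimeras, singleton rescue."""

import random

import pytest

from denovopost import (
    SequenceRecord,
    cluster_by_homolog,
    detect_chimeras,
    map_singletons,
    presence_venn,
    unique_homolog_counts,
)
from denovopost.records import BlastHit


def _hit(query, subject, evalue, db="NR", qs=1, qe=100):
    return BlastHit(
        query_id=query, db_name=db, subject_id=subject, percent_identity=90.0,
        align_length=qe - qs + 1, mismatches=0, gap_opens=0, query_start=qs,
        query_end=qe, subject_start=1, subject_end=33, evalue=evalue, bitscore=100.0,
    )


class TestClusterByHomolog:
    def test_basic_grouping(self):
        hits = [_hit("c1", "X", 1e-30), _hit("c2", "X", 1e-25)]
        clusters, multi = cluster_by_homolog(hits, "NR", 1e-20)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset({"c1", "c2"})
        assert multi == {}

    def test_cutoff_excludes(self):
        clusters, _ = cluster_by_homolog([_hit("c1", "X", 1e-10)], "NR", 1e-20)
        assert clusters == []

    def test_multi_membership_reported(self):
        hits = [_hit("c1", "X", 1e-30), _hit("c1", "Y", 1e-28), _hit("c2", "Y", 1e-30)]
        clusters, multi = cluster_by_homolog(hits, "NR", 1e-20)
        assert {c.subject_id: c.members for c in clusters} == {
            "X": frozenset({"c1"}), "Y": frozenset({"c1", "c2"}),
        }
        assert multi == {"c1": ["X", "Y"]}


class TestUniqueCounts:
    def test_counting_and_monotonicity(self):
        hits = [
            _hit("c1", "X", 1e-30), _hit("c2", "X", 1e-30), _hit("c3", "Y", 1e-30),
            _hit("c4", "Z", 1e-8),
        ]
        counts = unique_homolog_counts(hits)
        assert counts.at["NR", 1e-20] == 2
        assert counts.at["NR", 1e-5] == 3
        row = counts.loc["NR"]
        assert (row.diff().dropna() <= 0).all()

    def test_random_monotone(self):
        rng = random.Random(17)
        hits = [
            _hit(f"c{rng.randint(0, 50)}", f"S{rng.randint(0, 30)}",
                 10 ** -rng.uniform(3, 80), db=rng.choice(["NR", "HG"]))
            for _ in range(500)
        ]
        counts = unique_homolog_counts(hits)
        for db in counts.index:
            vals = counts.loc[db].tolist()
            assert vals == sorted(vals, reverse=True)

    def test_empty(self):
        counts = unique_homolog_counts([])
        assert counts.empty


class TestVenn:
    def test_regions_partition(self):
        hits = [
            _hit("c1", "X", 1e-30, db="NR"),
            _hit("c1", "X", 1e-30, db="HG"),
            _hit("c2", "Y", 1e-30, db="NR"),
            _hit("c3", "Z", 1e-3, db="NR"),  # fails cutoff
        ]
        per_seq, regions = presence_venn(hits, ["NR", "HG"], 1e-5)
        assert per_seq == {"c1": frozenset({"NR", "HG"}), "c2": frozenset({"NR"})}
        assert sum(regions.values()) == len(per_seq)

    def test_random_partition_property(self):
        rng = random.Random(18)
        dbs = ["NR", "HG", "UG", "AC"]
        hits = [
            _hit(f"c{rng.randint(0, 80)}", "S", 10 ** -rng.uniform(2, 40),
                 db=rng.choice(dbs))
            for _ in range(400)
        ]
        per_seq, regions = presence_venn(hits, dbs, 1e-5)
        assert sum(regions.values()) == len(per_seq)


class TestChimeras:
    def test_opposite_end_hits_called(self):
        hits = [
            _hit("c1", "geneA", 1e-40, qs=1, qe=300),
            _hit("c1", "geneB", 1e-30, qs=350, qe=650),
        ]
        calls = detect_chimeras(hits, query_lengths={"c1": 650})
        assert len(calls) == 1
        assert {calls[0].hit_a.subject_id, calls[0].hit_b.subject_id} == {
            "geneA", "geneB",
        }
        assert calls[0].query_gap == 49

    def test_same_subject_no_call(self):
        hits = [
            _hit("c1", "geneA", 1e-40, qs=1, qe=300),
            _hit("c1", "geneA", 1e-30, qs=350, qe=650),
        ]
        assert detect_chimeras(hits, query_lengths={"c1": 650}) == []

    def test_same_half_no_call(self):
        hits = [
            _hit("c1", "geneA", 1e-40, qs=1, qe=200),
            _hit("c1", "geneB", 1e-30, qs=210, qe=400),
        ]
        assert detect_chimeras(hits, query_lengths={"c1": 1000}) == []

    def test_weak_hits_no_call(self):
        hits = [
            _hit("c1", "geneA", 1e-10, qs=1, qe=300),
            _hit("c1", "geneB", 1e-30, qs=350, qe=650),
        ]
        assert detect_chimeras(hits, query_lengths={"c1": 650}) == []

    def test_overlapping_intervals_no_call(self):
        hits = [
            _hit("c1", "geneA", 1e-40, qs=1, qe=400),
            _hit("c1", "geneB", 1e-30, qs=300, qe=650),
        ]
        assert detect_chimeras(hits, query_lengths={"c1": 650}) == []

    def test_whitelist_suppression(self):
        hits = [
            _hit("c1", "mt-co1", 1e-40, qs=1, qe=300),
            _hit("c1", "mt-co2", 1e-30, qs=350, qe=650),
        ]
        assert detect_chimeras(hits, query_lengths={"c1": 650}) != []
        assert (
            detect_chimeras(
                hits, query_lengths={"c1": 650},
                whitelist={frozenset(("mt-co1", "mt-co2"))},
            )
            == []
        )

    def test_geometric_predicate_holds_posthoc(self, small_dataset):
        qlens = {c.id: len(c.residues) for c in small_dataset.contigs}
        calls = detect_chimeras(
            [h for h in small_dataset.blast_hits if h.db_name == "NR"],
            query_lengths=qlens,
        )
        for call in calls:
            assert call.hit_a.subject_id != call.hit_b.subject_id
            assert call.hit_a.evalue < 1e-20 and call.hit_b.evalue < 1e-20
            half = qlens[call.seq_id] / 2
            mid_a = (call.hit_a.query_start + call.hit_a.query_end) / 2
            mid_b = (call.hit_b.query_start + call.hit_b.query_end) / 2
            assert mid_a < half < mid_b


class TestMapSingletons:
    def _contig(self, rng, n=600, cid="c1"):
        return SequenceRecord(
            id=cid, residues="".join(rng.choice("ACGT") for _ in range(n))
        )

    def test_exact_substring_mapped(self):
        rng = random.Random(41)
        contig = self._contig(rng)
        s = SequenceRecord(id="s1", residues=contig.residues[100:400])
        (m,) = map_singletons([s], [contig])
        assert m.contig_id == "c1" and m.identity == 100.0
        assert m.unaligned_5p == 0 and m.unaligned_3p == 0

    def test_small_overhang_allowed_large_rejected(self):
        rng = random.Random(42)
        contig = self._contig(rng)
        tail = "".join(rng.choice("ACGT") for _ in range(4))
        ok = SequenceRecord(id="s1", residues=tail + contig.residues[100:400])
        res = map_singletons([ok], [contig])
        assert len(res) == 1 and res[0].unaligned_5p <= 4

        big_tail = "GTCA" * 5  # 20 bp foreign 5' end
        bad = SequenceRecord(id="s2", residues=big_tail + contig.residues[100:400])
        assert map_singletons([bad], [contig]) == []

    def test_low_identity_rejected(self):
        rng = random.Random(43)
        contig = self._contig(rng)
        frag = list(contig.residues[100:400])
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for pos in rng.sample(range(300), 20):  # 93.3% identity
            frag[pos] = swap[frag[pos]]
        s = SequenceRecord(id="s1", residues="".join(frag))
        assert map_singletons([s], [contig]) == []

    def test_random_singleton_not_mapped(self):
        rng = random.Random(44)
        contig = self._contig(rng)
        s = SequenceRecord(
            id="s1", residues="".join(rng.choice("ACGT") for _ in range(300))
        )
        assert map_singletons([s], [contig]) == []

    def test_best_contig_chosen(self):
        rng = random.Random(45)
        c1 = self._contig(rng, cid="c1")
        c2 = SequenceRecord(id="c2", residues=c1.residues[50:550])
        s = SequenceRecord(id="s1", residues=c1.residues[100:400])
        (m,) = map_singletons([s], [c1, c2])
        # both perfect: tie broken by lexicographically smaller contig id
        assert m.contig_id == "c1"
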