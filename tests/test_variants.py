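"""Variant filtering and selection statistics against brute-force recounts."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from denovopost import (
    OrfRecord,
    SequenceRecord,
    VariantRecord,
    classify_substitution,
    coding_effect,
    filter_variants,
    find_longest_orf,
    flag_highly_variable,
    regress_variants_on_length,
    selection_candidates,
    summarize_contig,
)
from denovopost.variants import ContigVariantSummary

from oracles import filter_oracle, is_ts_oracle


def _snp(contig="c1", pos=10, ref="A", alt="G", cov=20, prob=0.99):
    return VariantRecord(
        contig_id=contig, position=pos, ref_allele=ref, alt_allele=alt,
        var_type="SNP", coverage=cov, probability=prob,
    )


def _indel(contig="c1", pos=10, vtype="DEL", cov=20, prob=0.99, ref="A", alt="-"):
    if vtype == "INS":
        ref, alt = "-", "A"
    return VariantRecord(
        contig_id=contig, position=pos, ref_allele=ref, alt_allele=alt,
        var_type=vtype, coverage=cov, probability=prob,
    )


SEQ = "ACGTACGTAC" * 10  # no homopolymer runs
SEQS = {"c1": SEQ}


class TestFilter:
    @pytest.mark.parametrize(
        "cov,prob,kept",
        [
            (4, 0.99, False),   # coverage < 5 removed
            (5, 0.9, True),     # boundary values retained
            (100, 0.9, True),
            (101, 0.99, False),
            (20, 0.8999, False),
            (20, 0.9, True),
        ],
    )
    def test_boundary_semantics(self, cov, prob, kept):
        out = filter_variants([_snp(cov=cov, prob=prob)], SEQS)
        assert bool(out) is kept

    def test_homopolymer_indel_removed_snp_kept(self):
        seq = "ACGT" + "AAAA" + "CGTCGTCGTC" * 5
        seqs = {"c1": seq}
        for pos in (4, 5, 8, 9):  # flanking and inside the AAAA run
            assert filter_variants([_indel(pos=pos)], seqs) == []
        assert filter_variants([_snp(pos=6, ref="A", alt="G")], seqs) != []
        assert filter_variants([_indel(pos=12)], seqs) != []

    def test_unknown_contig_errors(self):
        with pytest.raises(KeyError, match="c9"):
            filter_variants([_snp(contig="c9")], SEQS)

    def test_matches_oracle_and_idempotent(self):
        rng = random.Random(55)
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        seqs = {"c1": seq}
        variants = []
        for _ in range(1000):
            pos = rng.randint(1, 500)
            if rng.random() < 0.5:
                ref = seq[pos - 1]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                variants.append(
                    _snp(pos=pos, ref=ref, alt=alt, cov=rng.randint(0, 130),
                         prob=rng.random())
                )
            else:
                variants.append(
                    _indel(pos=pos, vtype=rng.choice(["INS", "DEL"]),
                           cov=rng.randint(0, 130), prob=rng.random())
                )
        kept = filter_variants(variants, seqs)
        assert kept == filter_oracle(variants, seqs)
        assert filter_variants(kept, seqs) == kept


class TestSubstitution:
    def test_all_twelve_ordered_pairs(self):
        counts = {"TS": 0, "TV": 0}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref != alt:
                    kind = classify_substitution(ref, alt)
                    counts[kind] += 1
                    assert (kind == "TS") == is_ts_oracle(ref, alt)
        assert counts == {"TS": 4, "TV": 8}

    def test_errors(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")
        with pytest.raises(ValueError):
            classify_substitution("A", "N")


class TestCodingEffect:
    def test_known_codons(self):
        orf = OrfRecord(contig_id="c1", start=0, end=30, strand="+")
        # GAA->GAG at third codon position: Glu/Glu
        seq = "GAA" * 10
        snp = _snp(pos=3, ref="A", alt="G")
        assert coding_effect(snp, orf, seq) == "synonymous"
        # CGA->AGA at first codon position: Arg/Arg
        seq = "CGA" * 10
        snp = _snp(pos=1, ref="C", alt="A")
        assert coding_effect(snp, orf, seq) == "synonymous"
        # GAA->GTA: Glu->Val
        seq = "GAA" * 10
        snp = _snp(pos=2, ref="A", alt="T")
        assert coding_effect(snp, orf, seq) == "nonsynonymous"

    def test_outside_orf_noncoding(self):
        seq = "T" * 12 + "GAA" * 10 + "T" * 5
        orf = OrfRecord(contig_id="c1", start=12, end=42, strand="+")
        assert coding_effect(_snp(pos=5, ref="T", alt="A"), orf, seq) == "noncoding"

    def test_minus_strand(self):
        # forward contig holds the reverse complement of a GAA repeat ORF
        from Bio.Seq import Seq

        cds = "ATG" + "GAA" * 9
        seq = str(Seq(cds).reverse_complement())
        orf = OrfRecord(contig_id="c1", start=0, end=30, strand="-")
        # mutate the forward base that is the wobble A of a GAA codon:
        # forward position 1 corresponds to cds position 29 (third of codon 10)
        snp = _snp(pos=1, ref=seq[0], alt="C")  # cds A->G : GAA->GAG Glu/Glu
        assert coding_effect(snp, orf, seq) == "synonymous"

    def test_orf_exceeding_contig_errors(self):
        orf = OrfRecord(contig_id="c1", start=0, end=300, strand="+")
        with pytest.raises(ValueError, match="exceeds"):
            coding_effect(_snp(pos=1, ref="A", alt="G"), orf, "ACG" * 10)


class TestSummaries:
    def test_smoothed_ratios(self):
        contig = SequenceRecord(id="c1", residues="GAA" * 40)
        orf = OrfRecord(contig_id="c1", start=0, end=120, strand="+")
        s = summarize_contig(contig, [], orf)
        assert s.tstv_ratio == 1.0 and s.kaks_ratio == 1.0
        # 2 TS + 1 TV -> (2+1)/(1+1)
        vs = [
            _snp(pos=3, ref="A", alt="G"),   # TS, synonymous (GAA->GAG)
            _snp(pos=6, ref="A", alt="G"),   # TS, synonymous
            _snp(pos=8, ref="A", alt="T"),   # TV, nonsynonymous (GAA->GTA)
        ]
        s = summarize_contig(contig, vs, orf)
        assert s.tstv_ratio == pytest.approx(1.5)
        assert (s.ka, s.ks) == (1, 2)
        assert s.kaks_ratio == pytest.approx(2 / 3)
        assert s.ts + s.tv == s.n_snp
        assert s.density == pytest.approx(3 / 120)

    def test_kaks_only_with_orf(self):
        contig = SequenceRecord(id="c1", residues=SEQ)
        s = summarize_contig(contig, [_snp(pos=1, ref="A", alt="G")], None)
        assert s.kaks_ratio is None and s.ka is None

    def test_one_ka_zero_ks(self):
        contig = SequenceRecord(id="c1", residues="GAA" * 40)
        orf = OrfRecord(contig_id="c1", start=0, end=120, strand="+")
        s = summarize_contig(contig, [_snp(pos=2, ref="A", alt="T")], orf)
        assert s.kaks_ratio == pytest.approx(2.0)


class TestHighlyVariable:
    @staticmethod
    def _summary(cid, length, n):
        return ContigVariantSummary(
            contig_id=cid, length=length, n_snp=n, n_indel=0, ts=n, tv=0,
            ka=None, ks=None, tstv_ratio=float(n + 1), kaks_ratio=None,
            density=n / length, density_per_200bp=200 * n / length,
        )

    def test_distinct_densities_flag_exactly_one(self):
        summaries = [self._summary(f"c{i}", 1000, i + 1) for i in range(100)]
        flagged = flag_highly_variable(summaries, q=0.99)
        assert [s.contig_id for s in flagged] == ["c99"]

    def test_all_equal_all_flagged(self):
        summaries = [self._summary(f"c{i}", 1000, 5) for i in range(10)]
        assert len(flag_highly_variable(summaries)) == 10

    def test_invariant_under_permutation(self):
        rng = random.Random(66)
        summaries = [self._summary(f"c{i}", 1000, rng.randint(1, 60)) for i in range(200)]
        flagged_a = {s.contig_id for s in flag_highly_variable(list(summaries))}
        rng.shuffle(summaries)
        flagged_b = {s.contig_id for s in flag_highly_variable(summaries)}
        assert flagged_a == flagged_b


class TestRegression:
    def test_exact_fit(self):
        summaries = [
            TestHighlyVariable._summary("a", 100, 1),
            TestHighlyVariable._summary("b", 200, 2),
            TestHighlyVariable._summary("c", 300, 3),
        ]
        res = regress_variants_on_length(summaries)
        assert res.slope == pytest.approx(0.01)
        assert res.r2 == pytest.approx(1.0)

    def test_shift_changes_intercept_not_slope(self):
        rng = np.random.default_rng(9)
        lengths = rng.integers(100, 2000, 50)
        counts = (lengths * 0.01 + rng.normal(0, 1, 50)).round().clip(1).astype(int)
        base = [
            TestHighlyVariable._summary(f"c{i}", int(l), int(n))
            for i, (l, n) in enumerate(zip(lengths, counts))
        ]
        shifted = [
            TestHighlyVariable._summary(f"c{i}", int(l), int(n) + 5)
            for i, (l, n) in enumerate(zip(lengths, counts))
        ]
        r1 = regress_variants_on_length(base)
        r2 = regress_variants_on_length(shifted)
        assert r1.slope == pytest.approx(r2.slope)
        assert r2.intercept == pytest.approx(r1.intercept + 5)
        assert 0 <= r1.r2 <= 1

    def test_degenerate_errors(self):
        same = [TestHighlyVariable._summary(f"c{i}", 500, i + 1) for i in range(5)]
        with pytest.raises(ValueError, match="degenerate"):
            regress_variants_on_length(same)


class TestCandidates:
    def _summary(self, cid, kaks, tstv, flagged):
        s = TestHighlyVariable._summary(cid, 1000, 5)
        s.kaks_ratio = kaks
        s.tstv_ratio = tstv
        s.highly_variable = flagged
        return s

    def test_intersection_rule(self):
        s_in = self._summary("in", 1.5, 0.8, True)
        s_tstv = self._summary("no_tstv", 1.5, 1.2, True)
        s_flag = self._summary("no_flag", 1.5, 0.8, False)
        s_kaks = self._summary("no_kaks", 0.9, 0.8, True)
        out = selection_candidates([s_in, s_tstv, s_flag, s_kaks])
        assert [s.contig_id for s in out] == ["in"]

    def test_equals_explicit_intersection(self):
        rng = random.Random(13)
        summaries = [
            self._summary(
                f"c{i}", rng.uniform(0.3, 2.0), rng.uniform(0.3, 2.0),
                rng.random() < 0.3,
            )
            for i in range(300)
        ]
        got = {s.contig_id for s in selection_candidates(summaries)}
        a = {s.contig_id for s in summaries if s.kaks_ratio > 1}
        b = {s.contig_id for s in summaries if s.tstv_ratio < 1}
        c = {s.contig_id for s in summaries if s.highly_variable}
        assert got == a & b & c


class TestFindOrf:
    def test_short_orf_rejected(self):
        assert find_longest_orf("ATGAAATAG") is None

    def test_planted_orf_found(self):
        rng = random.Random(21)
        codons = "".join(
            rng.choice([c for c in ("GAA", "GCT", "CTG", "AAA", "TGC")])
            for _ in range(60)
        )
        seq = "CCCCC" + "ATG" + codons + "TAA" + "CCCCC"
        orf = find_longest_orf(seq)
        assert orf is not None
        assert seq[orf.start : orf.start + 3] == "ATG"
        assert (orf.end - orf.start) == 3 + 180 + 3
        assert orf.strand == "+"

    def test_minus_strand_orf(self):
        from Bio.Seq import Seq

        rng = random.Random(22)
        codons = "".join(rng.choice(["GAA", "GCT", "CTG"]) for _ in range(50))
        fwd = "ATG" + codons + "TGA"
        seq = "GGGG" + str(Seq(fwd).reverse_complement()) + "GGGG"
        orf = find_longest_orf(seq)
        assert orf is not None and orf.strand == "-"
        sub = seq[orf.start : orf.end]
        assert str(Seq(sub).reverse_complement()).startswith("ATG")

    def test_all_n_sequence(self):
        assert find_longest_orf("N" * 200) is None

    def test_exhaustive_scan_oracle(self):
        # brute force: try every (strand, start) and grow to the first stop
        from Bio.Seq import Seq

        rng = random.Random(23)
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(240))
            best = None
            for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
                for start in range(len(s) - 2):
                    if s[start : start + 3] != "ATG":
                        continue
                    for end in range(start + 3, len(s) - 2, 3):
                        codon = s[end : end + 3]
                        if codon in ("TAA", "TAG", "TGA"):
                            length = end + 3 - start
                            if length >= 30 and (best is None or length > best):
                                best = length
                            break
            orf = find_longest_orf(seq)
            got = (orf.end - orf.start) if orf else None
            assert got == best


@given(
    st.lists(
        st.tuples(
            st.integers(0, 130),
            st.floats(0, 1, allow_nan=False),
        ),
        min_size=1,
        max_size=50,
    )
)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_filter_idempotence_property(pairs):
    variants = [
        _snp(pos=(i % 100) + 1, ref=SEQ[i % 100], alt="G" if SEQ[i % 100] != "G" else "C",
             cov=cov, prob=prob)
        for i, (cov, prob) in enumerate(pairs)
    ]
    kept = filter_variants(variants, SEQS)
    assert filter_variants(kept, SEQS) == kept
    assert kept == filter_oracle(variants, SEQS)
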