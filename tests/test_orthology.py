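"""Internal k-mer search, best hits, RBH pairing, reference coverage."""

import numpy as np
import pytest

from xdeg.io_formats import HitRecord, SequenceRecord
from xdeg.orthology import (
    SearchParams,
    best_hits,
    kmer_search,
    reciprocal_best_hits,
    reference_coverage,
    transpose_hits,
)

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def hit(q="q1", s="s1", score=50.0, evalue=0.0, ident=95.0, length=100):
    return HitRecord(q, s, ident, length, 0, 0, 1, length, 1, length, evalue, score)


class TestKmerSearch:
    def test_identical_sequences_full_length_hit(self, rng):
        seq = rand_seq(rng, 100)
        (h,) = kmer_search(
            [SequenceRecord("q1", "X", seq, 2)], [SequenceRecord("s1", "Y", seq, 2)]
        )
        assert h.pct_identity == 100.0 and h.aln_length == 100
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 100, 1, 100)

    def test_no_shared_kmer_no_hit(self):
        p = SearchParams(min_aln_length=5, min_pct_identity=0.0)
        hits = kmer_search(
            [SequenceRecord("q1", "X", "A" * 40, 2)],
            [SequenceRecord("s1", "Y", "C" * 40, 2)],
            p,
        )
        assert hits == []

    def test_central_mismatch_spanned_by_extension(self, rng):
        # 101-nt pair differing at the centre: one hit over all 101 positions
        seq = rand_seq(rng, 101)
        other = list(seq)
        other[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[50]]
        (h,) = kmer_search(
            [SequenceRecord("q1", "X", seq, 2)],
            [SequenceRecord("s1", "Y", "".join(other), 2)],
        )
        assert h.aln_length == 101
        assert h.mismatches == 1
        assert h.pct_identity == pytest.approx(100 * 100 / 101, abs=0.01)
        assert h.bitscore == 101 - 3  # 100 matches - 2 for the mismatch

    def test_minus_strand_reports_descending_subject_coords(self, rng):
        seq = rand_seq(rng, 80)
        (h,) = kmer_search(
            [SequenceRecord("q1", "X", revcomp(seq), 2)],
            [SequenceRecord("s1", "Y", seq, 2)],
        )
        assert h.q_start < h.q_end and h.s_start > h.s_end
        assert h.pct_identity == 100.0 and h.aln_length == 80

    def test_k_larger_than_shortest_sequence_rejected(self):
        with pytest.raises(ValueError, match="shortest"):
            kmer_search(
                [SequenceRecord("q1", "X", "ACGTACGT", 2)],
                [SequenceRecord("s1", "Y", "ACGTACGTACGTACG", 2)],
                SearchParams(k=11),
            )

    def test_filters_suppress_short_or_divergent_hits(self, rng):
        seq = rand_seq(rng, 40)
        params = SearchParams(k=11, min_aln_length=50, min_pct_identity=80.0)
        hits = kmer_search(
            [SequenceRecord("q1", "X", seq, 2)], [SequenceRecord("s1", "Y", seq, 2)], params
        )
        assert hits == []  # identical, but shorter than min_aln_length


class TestBestHits:
    def test_max_score_wins(self):
        m = best_hits([hit(score=50.0, s="s1"), hit(score=40.0, s="s2")])
        assert m["q1"].subject_id == "s1"

    def test_tie_broken_by_evalue_then_subject_id(self):
        m = best_hits([hit(score=50, s="s2"), hit(score=50, s="s1")])
        assert m["q1"].subject_id == "s1"
        m = best_hits([hit(score=50, s="s1", evalue=1e-5), hit(score=50, s="s2", evalue=1e-9)])
        assert m["q1"].subject_id == "s2"

    def test_empty_input(self):
        assert best_hits([]) == {}


class TestReciprocalBestHits:
    def r(self, id, species, n=3):
        return SequenceRecord(id, species, "ACGTACGTACGT", n)

    def test_mutual_best_pairs(self):
        map_ab = best_hits([hit(q="a1", s="b1")])
        map_ba = best_hits([hit(q="b1", s="a1")])
        (p,) = reciprocal_best_hits(
            map_ab, map_ba, [self.r("a1", "A", 4)], [self.r("b1", "B", 7)]
        )
        assert (p.id_a, p.id_b, p.reads_a, p.reads_b) == ("a1", "b1", 4, 7)

    def test_non_mutual_best_not_paired(self):
        map_ab = best_hits([hit(q="a1", s="b1")])
        map_ba = best_hits([hit(q="b1", s="a2")])
        recs_a = [self.r("a1", "A"), self.r("a2", "A")]
        assert reciprocal_best_hits(map_ab, map_ba, recs_a, [self.r("b1", "B")]) == []

    def test_unknown_id_rejected(self):
        map_ab = best_hits([hit(q="a9", s="b1")])
        with pytest.raises(KeyError):
            reciprocal_best_hits(map_ab, {}, [self.r("a1", "A")], [self.r("b1", "B")])

    def test_symmetric_under_species_exchange(self, small_dataset):
        # the RBH pair set is the same whichever species is the query side
        _, records_a, records_b, _ = small_dataset
        params = SearchParams()
        hits_ab = kmer_search(records_a, records_b, params)
        hits_ba = kmer_search(records_b, records_a, params)
        map_ab, map_ba = best_hits(hits_ab), best_hits(hits_ba)
        fwd = reciprocal_best_hits(map_ab, map_ba, records_a, records_b)
        rev = reciprocal_best_hits(map_ba, map_ab, records_b, records_a)
        assert {(p.id_a, p.id_b) for p in fwd} == {(p.id_b, p.id_a) for p in rev}

    def test_recovers_true_pairs_on_synthetic_data(self, small_dataset):
        # with <= 5% divergence and no paralogs, RBH finds nearly all
        # doubly-observed ortholog pairs
        _, records_a, records_b, truth = small_dataset
        hits_ab = kmer_search(records_a, records_b)
        pairs = reciprocal_best_hits(
            best_hits(hits_ab), best_hits(transpose_hits(hits_ab)), records_a, records_b
        )
        found = {(p.id_a, p.id_b) for p in pairs}
        expected = {
            (f"A_{r.gene_id}", f"B_{r.gene_id}")
            for r in truth.itertuples()
            if r.cls == "shared" and r.count_a > 0 and r.count_b > 0
        }
        assert len(expected) > 100
        assert len(found & expected) / len(expected) >= 0.99


class TestTransposeHits:
    def test_transpose_is_involution_and_swaps_roles(self):
        h = HitRecord("q", "s", 95.0, 60, 3, 0, 5, 64, 120, 61, 0.0, 51.0)
        (t,) = transpose_hits([h])
        assert t.query_id == "s" and t.subject_id == "q"
        assert t.q_start <= t.q_end and t.s_start > t.s_end  # minus kept
        (back,) = transpose_hits([t])
        assert back == h


class TestReferenceCoverage:
    def test_single_hit_fraction(self):
        h = HitRecord("c1", "ref1", 99.0, 73, 0, 0, 1, 73, 1, 73, 0.0, 73.0)
        cov = reference_coverage([h], {"ref1": 100})
        assert cov["ref1"] == pytest.approx(0.73)

    def test_overlaps_counted_once(self):
        h1 = HitRecord("c1", "ref1", 99.0, 50, 0, 0, 1, 50, 1, 50, 0.0, 50.0)
        h2 = HitRecord("c2", "ref1", 99.0, 50, 0, 0, 1, 50, 26, 75, 0.0, 50.0)
        cov = reference_coverage([h1, h2], {"ref1": 100})
        assert cov["ref1"] == pytest.approx(0.75)

    def test_reference_without_hits_zero(self):
        assert reference_coverage([], {"ref1": 100}) == {"ref1": 0.0}

    def test_out_of_range_coordinates_rejected(self):
        h = HitRecord("c1", "ref1", 99.0, 73, 0, 0, 1, 73, 50, 122, 0.0, 73.0)
        with pytest.raises(ValueError):
            reference_coverage([h], {"ref1": 100})
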