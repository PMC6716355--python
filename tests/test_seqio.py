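"""Read-processing tests: merge, QC, demultiplex, dereplicate, round trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casecomm import enumerate_design, make_stage_profiles, simulate_counts
from casecomm.seqio import (
    PairedRead,
    demultiplex,
    dereplicate,
    merge_pair,
    process_fastq,
    qc_filter,
    revcomp,
)
from casecomm.synthetic import FWD_PRIMER, REV_PRIMER, default_barcode_map, write_fastq_pairs

RNG = np.random.default_rng(123)


def random_dna(n, rng=RNG):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def pair_with_overlap(amplicon: str, read_len: int, q1: int = 38, q2: int = 30) -> PairedRead:
    """Mates reading both ends of ``amplicon`` with the implied overlap."""
    s1 = amplicon[:read_len]
    s2 = revcomp(amplicon)[:read_len]
    return PairedRead("r", s1, np.full(read_len, q1), s2, np.full(read_len, q2))


class TestMergePair:
    def test_exact_overlap_length(self):
        amplicon = random_dna(180)  # reads 100 bp -> 20 bp overlap
        pair = pair_with_overlap(amplicon, 100)
        merged = merge_pair(pair)
        assert merged is not None
        assert merged.seq == amplicon
        assert len(merged.seq) == 100 + 100 - 20

    def test_overlap_below_minimum_rejected(self):
        amplicon = random_dna(191)  # reads 100 bp -> best true overlap 9 bp
        pair = pair_with_overlap(amplicon, 100)
        assert merge_pair(pair) is None

    def test_mismatch_resolved_by_higher_quality(self):
        amplicon = random_dna(150)
        pair = pair_with_overlap(amplicon, 100)  # 50 bp overlap
        # corrupt mate 2 inside the overlap; mate 1 has higher quality
        pos = 75  # amplicon coordinate inside the 50-bp overlap [50, 100)
        rc = revcomp(amplicon)
        j = 149 - pos  # position in mate 2
        wrong = {"A": "C", "C": "G", "G": "T", "T": "A"}[rc[j]]
        s2 = rc[:j] + wrong + rc[j + 1 : 100]
        pair = PairedRead("r", pair.seq1, pair.qual1, s2, pair.qual2)
        merged = merge_pair(pair)
        assert merged.seq == amplicon  # mate 1 base won
        # now give mate 2 the higher quality: its (wrong) base must win
        pair2 = PairedRead("r", pair.seq1, np.full(100, 20), s2, np.full(100, 39))
        merged2 = merge_pair(pair2)
        assert merged2.seq != amplicon
        # mate 2 is stored reverse-complemented, so its planted base appears
        # complemented in the merged scaffold
        assert merged2.seq[pos] == {"A": "T", "C": "G", "G": "C", "T": "A"}[wrong]

    def test_merged_quality_is_columnwise_max(self):
        amplicon = random_dna(150)
        pair = pair_with_overlap(amplicon, 100, q1=31, q2=36)
        merged = merge_pair(pair)
        assert merged.qual[:50].max() == 31
        assert (merged.qual[100:150] == 36).all()  # overlap: max(31, 36)

    def test_empty_mate_raises(self):
        with pytest.raises(ValueError):
            merge_pair(PairedRead("r", "", np.array([]), "ACGT", np.full(4, 30)))


class TestQcFilter:
    @pytest.mark.parametrize(
        "seq,qual,expected",
        [
            (random_dna(199), np.full(199, 38), "length"),
            (random_dna(250), np.full(250, 30), "quality"),
            (random_dna(249) + "N", np.full(250, 38), "ambiguous"),
        ],
    )
    def test_failure_reasons(self, seq, qual, expected):
        result = qc_filter(seq, qual)
        assert not result.passed
        assert result.reason == expected

    def test_pass(self):
        result = qc_filter(random_dna(250), np.full(250, 38))
        assert result.passed and result.reason is None

    @given(st.integers(200, 300), st.integers(0, 41))
    @settings(max_examples=30, deadline=None)
    def test_pure_function(self, length, q):
        seq = "A" * length
        qual = np.full(length, q)
        first = qc_filter(seq, qual)
        assert qc_filter(seq, qual) == first  # order/state independent


class TestDemultiplex:
    BC = {"s1": "AAAAAA", "s2": "CCCCCC"}

    def make_pair(self, bc1, bc2, fwd=FWD_PRIMER, rev=REV_PRIMER):
        body = random_dna(80)
        s1 = bc1 + fwd + body
        s2 = bc2 + rev + revcomp(body)[:80]
        return PairedRead("r1", s1, np.full(len(s1), 38), s2, np.full(len(s2), 38))

    def test_perfect_match_assigned_and_trimmed(self):
        pair = self.make_pair("AAAAAA", "AAAAAA")
        assigned, discarded = demultiplex([pair], self.BC, FWD_PRIMER, REV_PRIMER)
        assert not discarded
        (kept,) = assigned["s1"]
        assert len(kept.seq1) == 80
        assert not kept.seq1.startswith("AAAAAA" + FWD_PRIMER)

    def test_one_mismatch_in_barcode_discarded(self):
        pair = self.make_pair("AAAAAT", "AAAAAT")
        assigned, discarded = demultiplex([pair], self.BC, FWD_PRIMER, REV_PRIMER)
        assert sum(len(v) for v in assigned.values()) == 0
        assert discarded == [("r1", "barcode")]

    def test_primer_mismatch_discarded(self):
        bad_fwd = "T" + FWD_PRIMER[1:]
        pair = self.make_pair("AAAAAA", "AAAAAA", fwd=bad_fwd)
        _, discarded = demultiplex([pair], self.BC, FWD_PRIMER, REV_PRIMER)
        assert discarded == [("r1", "fwd_primer")]

    def test_empty_input(self):
        assigned, discarded = demultiplex([], self.BC, FWD_PRIMER, REV_PRIMER)
        assert sum(len(v) for v in assigned.values()) == 0 and discarded == []

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], {"a": "AAAAAA", "b": "AAAAAA"}, FWD_PRIMER, REV_PRIMER)

    def test_wrong_length_barcode_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], {"a": "AAAA"}, FWD_PRIMER, REV_PRIMER)


class TestDereplicate:
    def test_collapses_identical_strings(self):
        table = dereplicate({"A": ["ACGT" * 10] * 3, "B": ["ACGT" * 10] * 2})
        assert table.counts.shape == (1, 2)
        assert list(table.counts.iloc[0]) == [3, 2]

    def test_all_distinct(self):
        seqs = [random_dna(40) for _ in range(5)]
        table = dereplicate({"A": seqs})
        assert table.counts.shape == (5, 1)
        assert set(table.sequences.values()) == set(seqs)

    def test_preserves_per_sample_totals(self):
        per_sample = {"A": [random_dna(30) for _ in range(17)],
                      "B": [random_dna(30) for _ in range(9)]}
        table = dereplicate(per_sample)
        assert table.library_sizes["A"] == 17
        assert table.library_sizes["B"] == 9

    def test_row_order_invariant_to_input_order(self):
        seqs = [random_dna(30) for _ in range(6)]
        t1 = dereplicate({"A": seqs})
        t2 = dereplicate({"A": seqs[::-1]})
        assert list(t1.sequences.values()) == list(t2.sequences.values())


class TestRoundTrip:
    def test_error_free_fastq_reconstructs_table(self, tmp_path):
        design = enumerate_design()[:4]
        prof = make_stage_profiles(12, seed=2)
        table, _ = simulate_counts(design, prof, n_contaminants=3,
                                   depth_range=(60, 90), seed=5)
        barcodes = default_barcode_map(table.sample_ids)
        r1, r2 = write_fastq_pairs(table, barcodes, tmp_path / "r1.fq",
                                   tmp_path / "r2.fq", error_rate=0.0, seed=1)
        rebuilt, acct, log = process_fastq(r1, r2, barcodes, FWD_PRIMER, REV_PRIMER,
                                           control_ids=table.control_ids)
        acct.check()
        assert acct.demux_discarded == 0 and acct.merge_rejected == 0
        by_seq_orig = {table.sequences[i]: table.counts.loc[i].to_dict()
                       for i in table.counts.index}
        by_seq_new = {rebuilt.sequences[i]: rebuilt.counts.loc[i].to_dict()
                      for i in rebuilt.counts.index}
        assert by_seq_orig == by_seq_new

    def test_fastq_writer_deterministic(self, tmp_path):
        design = enumerate_design()[:2]
        prof = make_stage_profiles(10, seed=0)
        table, _ = simulate_counts(design, prof, depth_range=(30, 40), seed=2)
        barcodes = default_barcode_map(table.sample_ids)
        pa = write_fastq_pairs(table, barcodes, tmp_path / "a1.fq", tmp_path / "a2.fq",
                               error_rate=0.02, seed=4)
        pb = write_fastq_pairs(table, barcodes, tmp_path / "b1.fq", tmp_path / "b2.fq",
                               error_rate=0.02, seed=4)
        assert pa[0].read_bytes() == pb[0].read_bytes()
        assert pa[1].read_bytes() == pb[1].read_bytes()

    def test_bad_barcode_length_raises(self, tmp_path):
        design = enumerate_design()[:1]
        prof = make_stage_profiles(10, seed=0)
        table, _ = simulate_counts(design, prof, depth_range=(5, 8), seed=2)
        with pytest.raises(ValueError, match="length"):
            write_fastq_pairs(table, {table.sample_ids[0]: "ACGT"},
                              tmp_path / "x1.fq", tmp_path / "x2.fq")
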