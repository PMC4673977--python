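"""Pileup matrix accumulation: CIGAR walking, strand assignment, candidates."""

import numpy as np
import pysam
import pytest

from bsvar.bisulfite import BASE_INDEX, CRICK, WATSON
from bsvar.filters import FilterParams
from bsvar.pileup import (ChromMatrix, StrandBaseProfile, accumulate_pair,
                          accumulate_read, emit_candidates,
                          infer_bisulfite_strand)

from conftest import make_sam


def _reads(tmp_path, read_tuples, **kw):
    path = make_sam(tmp_path / "in.sam", read_tuples, **kw)
    with pysam.AlignmentFile(path) as af:
        return list(af)


class TestMatrixAllocation:
    def test_zero_initialized(self):
        m = ChromMatrix("chr1", 10)
        assert m.counts.shape == (10, 2, 4)
        assert not m.counts.any() and not m.qual_sums.any()

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            ChromMatrix("chrM", 0)

    def test_release_frees_storage(self):
        m = ChromMatrix("chr2", 100)
        m.release()
        assert m.counts.size == 0
        m2 = ChromMatrix("chr3", 50)
        assert m2.counts.shape[0] == 50


class TestAccumulate:
    def test_full_match_counts_each_base(self, tmp_path):
        (read,) = _reads(tmp_path, [("r", 0, 0, 60, "4M", "ACGT", None, {})])
        m = ChromMatrix("chr1", 10)
        accumulate_read(m, read, WATSON, 15)
        for offset, base in enumerate("ACGT"):
            assert m.counts[offset, WATSON, BASE_INDEX[base]] == 1
            assert m.qual_sums[offset, WATSON, BASE_INDEX[base]] == 30
        assert m.counts.sum() == 4

    def test_insertion_consumes_query_only(self, tmp_path):
        # manual CIGAR walk: 2M1I1M places bases at reference offsets 0,1,2
        (read,) = _reads(tmp_path, [("r", 0, 0, 60, "2M1I1M", "AACC", None, {})])
        m = ChromMatrix("chr1", 10)
        accumulate_read(m, read, WATSON, 15)
        assert m.counts[0, WATSON, BASE_INDEX["A"]] == 1
        assert m.counts[1, WATSON, BASE_INDEX["A"]] == 1
        assert m.counts[2, WATSON, BASE_INDEX["C"]] == 1   # base after insertion
        assert m.counts.sum() == 3

    def test_deletion_advances_reference(self, tmp_path):
        # 2M2D2M: bases at offsets 0,1,4,5; the deleted 2,3 untouched
        (read,) = _reads(tmp_path, [("r", 0, 0, 60, "2M2D2M", "ACGT", None, {})])
        m = ChromMatrix("chr1", 10)
        accumulate_read(m, read, WATSON, 15)
        occupied = sorted(np.nonzero(m.counts.sum(axis=(1, 2)))[0])
        assert occupied == [0, 1, 4, 5]

    def test_soft_clip_ignored(self, tmp_path):
        (read,) = _reads(tmp_path, [("r", 0, 5, 60, "2S2M", "ACGT", None, {})])
        m = ChromMatrix("chr1", 10)
        accumulate_read(m, read, CRICK, 15)
        occupied = sorted(np.nonzero(m.counts.sum(axis=(1, 2)))[0])
        assert occupied == [5, 6]
        assert m.counts[:, WATSON].sum() == 0

    def test_base_quality_floor_drops_bases(self, tmp_path):
        # qualities 10,40,10,40 with floor 15: only offsets 1 and 3 count
        qual = pysam.qualities_to_qualitystring([10, 40, 10, 40])
        (read,) = _reads(tmp_path, [("r", 0, 0, 60, "4M", "ACGT", qual, {})])
        m = ChromMatrix("chr1", 10)
        accumulate_read(m, read, WATSON, 15)
        occupied = sorted(np.nonzero(m.counts.sum(axis=(1, 2)))[0])
        assert occupied == [1, 3]
        assert m.qual_sums[1, WATSON, BASE_INDEX["C"]] == 40

    def test_n_bases_dropped(self, tmp_path):
        (read,) = _reads(tmp_path, [("r", 0, 0, 60, "4M", "ANGT", None, {})])
        m = ChromMatrix("chr1", 10)
        accumulate_read(m, read, WATSON, 15)
        assert m.counts.sum() == 3
        assert m.counts[1].sum() == 0

    def test_read_beyond_bounds_is_coordinate_error(self, tmp_path):
        (read,) = _reads(tmp_path, [("r", 0, 8, 60, "4M", "ACGT", None, {})])
        with pytest.raises(IndexError):
            accumulate_read(ChromMatrix("chr1", 10), read, WATSON, 15)

    def test_order_independence(self, tmp_path):
        tuples = [(f"r{i}", 0, i % 5, 60, "4M", "ACGT", None, {}) for i in range(20)]
        reads = _reads(tmp_path, tuples, length=100)
        m1 = ChromMatrix("chr1", 100)
        m2 = ChromMatrix("chr1", 100)
        for r in reads:
            accumulate_read(m1, r, WATSON, 15)
        for r in reversed(reads):
            accumulate_read(m2, r, WATSON, 15)
        assert np.array_equal(m1.counts, m2.counts)
        assert np.array_equal(m1.qual_sums, m2.qual_sums)


class TestPairOverlap:
    def test_overlapping_mates_counted_once_higher_quality_wins(self, tmp_path):
        q_low = pysam.qualities_to_qualitystring([20] * 4)
        q_high = pysam.qualities_to_qualitystring([35] * 4)
        reads = _reads(tmp_path, [
            ("p", 0x63, 0, 60, "4M", "ACGT", q_low, {}),
            ("p", 0x93, 2, 60, "4M", "TTTT", q_high, {}),
        ])
        m = ChromMatrix("chr1", 10)
        accumulate_pair(m, reads[0], reads[1], WATSON, 15)
        # offsets 2,3 overlap: the higher-quality mate's T wins
        assert m.counts[2, WATSON, BASE_INDEX["T"]] == 1
        assert m.counts[2, WATSON, BASE_INDEX["G"]] == 0
        assert m.counts.sum() == 6  # 2 + 2 overlapped-once + 2


class TestStrandInference:
    def test_bsmap_zs_tag(self, tmp_path):
        reads = _reads(tmp_path, [
            ("w", 0, 0, 60, "4M", "ACGT", None, {"ZS": "++"}),
            ("c", 16, 0, 60, "4M", "ACGT", None, {"ZS": "-+"}),
        ])
        assert infer_bisulfite_strand(reads[0]) == (WATSON, False)
        assert infer_bisulfite_strand(reads[1]) == (CRICK, False)

    def test_bismark_xg_tag(self, tmp_path):
        reads = _reads(tmp_path, [
            ("w", 0, 0, 60, "4M", "ACGT", None, {"XG": "CT"}),
            ("c", 16, 0, 60, "4M", "ACGT", None, {"XG": "GA"}),
        ])
        assert infer_bisulfite_strand(reads[0]) == (WATSON, False)
        assert infer_bisulfite_strand(reads[1]) == (CRICK, False)

    def test_flag_fallback_flags_the_read(self, tmp_path):
        reads = _reads(tmp_path, [
            ("s", 16, 0, 60, "4M", "ACGT", None, {}),
            ("p2", 0x93, 0, 60, "4M", "ACGT", None, {}),  # read2 reverse
        ])
        assert infer_bisulfite_strand(reads[0]) == (CRICK, True)
        # reverse read2 pairs with a forward read1 -> Watson template
        assert infer_bisulfite_strand(reads[1]) == (WATSON, True)


class TestEmitCandidates:
    def _matrix(self, profiles, length=50):
        m = ChromMatrix("chr1", length)
        for pos, (watson, crick) in profiles.items():
            p = StrandBaseProfile.from_counts(watson=watson, crick=crick)
            m.counts[pos, WATSON] = p.watson_count
            m.counts[pos, CRICK] = p.crick_count
            m.qual_sums[pos, WATSON] = p.watson_qual_sum
            m.qual_sums[pos, CRICK] = p.crick_qual_sum
        return m

    def test_pure_reference_position_not_yielded(self):
        m = self._matrix({3: ({"A": 10}, {})})
        assert list(emit_candidates(m, "A" * 50, FilterParams())) == []

    def test_frequency_at_default_threshold_yielded(self):
        # freq 0.2 >= 0.1 default
        m = self._matrix({3: ({"A": 8, "G": 2}, {})})
        out = list(emit_candidates(m, "A" * 50, FilterParams()))
        assert [pos for pos, _, _ in out] == [3]

    def test_frequency_below_threshold_suppressed(self):
        # freq 0.05 < 0.1
        m = self._matrix({3: ({"A": 19, "G": 1}, {})})
        assert list(emit_candidates(m, "A" * 50, FilterParams())) == []

    def test_positions_ascend(self):
        m = self._matrix({7: ({"A": 5, "G": 5}, {}), 2: ({"A": 5, "G": 5}, {})})
        out = [pos for pos, _, _ in emit_candidates(m, "A" * 50, FilterParams())]
        assert out == [2, 7]

    def test_short_reference_is_coordinate_error(self):
        m = self._matrix({3: ({"A": 8, "G": 2}, {})})
        with pytest.raises(IndexError):
            list(emit_candidates(m, "A" * 10, FilterParams()))
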