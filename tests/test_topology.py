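import numpy as np
import pytest
from hypothesis import given, strategies as st

from memsa.seqio import AMINO_ACIDS, SequenceRecord
from memsa.topology import (
    TopologyAnnotation,
    TopologyPredictorParams,
    TopologySegment,
    classify_by_tm_count,
    hydropathy_profile,
    predict_topology,
    segment_sequence,
)


class TestHydropathyProfile:
    def test_window_one_is_the_raw_scale(self):
        assert np.allclose(hydropathy_profile("AIR", 1), [1.8, 4.5, -4.5])

    def test_uniform_sequence_is_flat(self):
        assert np.allclose(hydropathy_profile("III", 3), [4.5, 4.5, 4.5])

    def test_window_truncated_at_ends(self):
        assert np.allclose(hydropathy_profile("A", 19), [1.8])
        # at position 0 of "AI" with window 3 only two residues are available
        assert np.allclose(hydropathy_profile("AI", 3), [(1.8 + 4.5) / 2] * 2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_profile("", 3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_profile("AIR", 4)


class TestPredictTopology:
    def test_planted_hydrophobic_run_recovered(self):
        rec = SequenceRecord("p", "R" * 10 + "I" * 21 + "R" * 10)
        ann = predict_topology(rec)
        tms = ann.tm_segments()
        assert len(tms) == 1
        assert abs(tms[0].start - 10) <= 3
        assert abs(tms[0].end - 31) <= 3

    def test_all_polar_has_no_helix(self):
        ann = predict_topology(SequenceRecord("p", "R" * 40))
        assert ann.tm_count == 0
        assert [s.label for s in ann.segments] == ["outside"]
        assert ann.length == 40

    def test_long_hydrophobic_run_split_to_helix_range(self):
        ann = predict_topology(SequenceRecord("p", "I" * 200))
        params = TopologyPredictorParams()
        for s in ann.tm_segments():
            assert params.min_helix_len <= s.length <= params.max_helix_len
        assert ann.tm_count >= 1

    def test_loops_alternate_outside_then_inside(self):
        seq = "R" * 10 + "I" * 21 + "R" * 10 + "I" * 21 + "R" * 10
        ann = predict_topology(SequenceRecord("p", seq))
        labels = [s.label for s in ann.segments]
        assert labels == ["outside", "TMhelix", "inside", "TMhelix", "outside"]


class TestSegmentSequence:
    def test_direct_slicing(self):
        rec = SequenceRecord("r", "ACDEFGHIKL")
        ann = TopologyAnnotation(
            "r",
            [
                TopologySegment("outside", 0, 4),
                TopologySegment("TMhelix", 4, 8),
                TopologySegment("inside", 8, 10),
            ],
        )
        seg = segment_sequence(rec, ann)
        assert seg.region_strings == [
            ("outside", "ACDE"),
            ("TMhelix", "FGHI"),
            ("inside", "KL"),
        ]

    def test_single_segment_is_whole_sequence(self):
        rec = SequenceRecord("r", "ACDE")
        ann = TopologyAnnotation("r", [TopologySegment("outside", 0, 4)])
        assert segment_sequence(rec, ann).region_strings == [("outside", "ACDE")]

    def test_length_mismatch_rejected(self):
        rec = SequenceRecord("r", "ACDE")
        ann = TopologyAnnotation("r", [TopologySegment("outside", 0, 3)])
        with pytest.raises(ValueError, match="length"):
            segment_sequence(rec, ann)


class TestClassifyByTmCount:
    @staticmethod
    def _fake(tm_count, rid):
        residues = "R" * 5 + ("I" * 20 + "R" * 5) * tm_count
        rec = SequenceRecord(rid, residues if tm_count else "R" * 5)
        return segment_sequence(rec, predict_topology(rec))

    def test_majority_count_wins(self):
        segs = [self._fake(c, f"s{i}") for i, c in enumerate([7, 7, 7, 2])]
        groups, dominant = classify_by_tm_count(segs)
        assert dominant == 7
        assert len(groups[7]) == 3 and len(groups[2]) == 1

    def test_tie_breaks_toward_larger_count(self):
        segs = [self._fake(3, "a"), self._fake(5, "b")]
        _, dominant = classify_by_tm_count(segs)
        assert dominant == 5

    def test_all_soluble_dominant_is_zero(self):
        segs = [self._fake(0, "a"), self._fake(0, "b")]
        _, dominant = classify_by_tm_count(segs)
        assert dominant == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_by_tm_count([])


class TestAnnotationInvariants:
    def test_adjacent_same_label_rejected_unless_merged(self):
        segs = [TopologySegment("outside", 0, 5), TopologySegment("outside", 5, 9)]
        with pytest.raises(ValueError):
            TopologyAnnotation("r", segs)
        merged = TopologyAnnotation.from_segments("r", segs)
        assert len(merged.segments) == 1

    def test_gap_between_segments_rejected(self):
        with pytest.raises(ValueError):
            TopologyAnnotation(
                "r", [TopologySegment("outside", 0, 5), TopologySegment("TMhelix", 6, 25)]
            )


@given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=200))
def test_prediction_always_segments_cleanly(seq):
    """Any predicted annotation tiles its sequence; slicing round-trips."""
    rec = SequenceRecord("r", seq)
    ann = predict_topology(rec)
    assert ann.length == len(seq)
    seg = segment_sequence(rec, ann)
    assert "".join(s for _, s in seg.region_strings) == seq
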