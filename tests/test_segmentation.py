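"""Segmentation techniques and label-assignment semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgbench.annotations import EXCLUDED
from ecgbench.io import BeatAnnotation, EcgRecord, RecordingLabel, RhythmEpisode
from ecgbench.segmentation import (
    WindowingParams,
    aggregate_predictions,
    label_window,
    segment_beats,
    segment_episodes,
    segment_recording_windows,
    segment_sliding,
    whole_sequence,
    window_count,
)

from .oracles import brute_force_window_label, enumerate_windows, random_annotation_stream


def _rec(n=10000, fs=250.0, rid="r0", pid="p0"):
    return EcgRecord(rid, pid, np.arange(float(n)), fs, "II")


class TestSegmentBeats:
    def test_window_length_072s_at_360hz_is_259(self, label_dict, form_task):
        rec = _rec(n=2000, fs=360.0)
        beats = [BeatAnnotation(1000, "N")]
        segs = segment_beats(rec, beats, 0.72, label_dict, form_task, "synth")
        assert len(segs) == 1
        assert segs[0].samples.size == 259  # round(0.72 * 360)

    def test_per_beat_labels_follow_symbols(self, label_dict, form_task):
        rec = _rec(n=5000, fs=250.0)
        beats = [BeatAnnotation(s, sym) for s, sym in
                 ((1000, "N"), (2000, "V"), (3000, "N"))]
        segs = segment_beats(rec, beats, 0.72, label_dict, form_task, "synth")
        assert [s.label for s in segs] == [0, 2, 0]  # N, VEB, N

    def test_boundary_beats_dropped(self, label_dict, form_task):
        rec = _rec(n=2000, fs=360.0)
        beats = [BeatAnnotation(10, "N"), BeatAnnotation(1995, "N"),
                 BeatAnnotation(1000, "N")]
        segs = segment_beats(rec, beats, 0.72, label_dict, form_task, "synth")
        assert len(segs) == 1 and segs[0].start == 1000 - 259 // 2

    def test_one_segment_per_interior_beat(self, label_dict, form_task):
        rec = _rec(n=20000, fs=250.0)
        w = round(0.72 * 250)
        interior = [b for b in range(500, 19500, 400)]
        beats = [BeatAnnotation(b, "N") for b in interior]
        segs = segment_beats(rec, beats, 0.72, label_dict, form_task, "synth")
        assert len(segs) == len(interior)
        assert all(s.samples.size == w for s in segs)

    def test_unknown_and_excluded_symbols_dropped(self, label_dict, form_task):
        rec = _rec(n=5000)
        beats = [BeatAnnotation(1000, "?"), BeatAnnotation(2000, "N")]
        segs = segment_beats(rec, beats, 0.72, label_dict, form_task, "synth")
        assert len(segs) == 1


class TestSegmentEpisodes:
    def test_span_lengths(self, label_dict, rhythm_task):
        rec = _rec(n=12000)
        eps = [RhythmEpisode(0, 5000, "N"), RhythmEpisode(5000, 12000, "AFIB")]
        segs = segment_episodes(rec, eps, label_dict, rhythm_task, "synth")
        assert [s.samples.size for s in segs] == [5000, 7000]
        assert [s.label for s in segs] == [1, 0]

    def test_overlapping_episodes_rejected(self, label_dict, rhythm_task):
        rec = _rec(n=1000)
        eps = [RhythmEpisode(0, 600, "N"), RhythmEpisode(500, 1000, "AFIB")]
        with pytest.raises(ValueError, match="overlap"):
            segment_episodes(rec, eps, label_dict, rhythm_task, "synth")

    def test_unknown_episode_symbol_yields_nothing(self, label_dict, rhythm_task):
        rec = _rec(n=1000)
        segs = segment_episodes(rec, [RhythmEpisode(0, 1000, "??")],
                                label_dict, rhythm_task, "synth")
        assert segs == []


class TestLabelWindow:
    def test_form_single_abnormal_beat_dominates(self, label_dict, form_task):
        beats = [BeatAnnotation(i, s) for i, s in
                 ((10, "N"), (20, "N"), (30, "V"), (40, "N"))]
        assert label_window((0, 100), beats, [], label_dict, form_task, "synth") == 2

    def test_rhythm_majority_coverage_wins(self, label_dict, rhythm_task):
        eps = [RhythmEpisode(0, 60, "AFIB"), RhythmEpisode(60, 100, "N")]
        assert label_window((0, 100), [], eps, label_dict, rhythm_task, "synth") == 0

    def test_form_all_normal_is_normal(self, label_dict, form_task):
        beats = [BeatAnnotation(i, "N") for i in (10, 20, 30)]
        assert label_window((0, 100), beats, [], label_dict, form_task, "synth") == 0

    def test_form_abnormal_tie_goes_to_rarer_class(self, label_dict, form_task):
        beats = [BeatAnnotation(10, "A"), BeatAnnotation(20, "V")]
        # VEB globally rarer than SVEB -> VEB wins
        counts = np.array([100, 50, 10])
        assert label_window((0, 100), beats, [], label_dict, form_task, "synth",
                            class_counts=counts) == 2
        # and the other way around
        counts = np.array([100, 10, 50])
        assert label_window((0, 100), beats, [], label_dict, form_task, "synth",
                            class_counts=counts) == 1

    def test_windows_without_evidence_excluded(self, label_dict, form_task, rhythm_task):
        assert label_window((0, 100), [], [], label_dict, form_task, "synth") == EXCLUDED
        assert label_window((0, 100), [], [], label_dict, rhythm_task, "synth") == EXCLUDED


class TestSlidingWindows:
    def test_derived_window_count(self, label_dict, rhythm_task):
        # L=6500, 2.5 s at 250 Hz -> w=625, 50% overlap -> s=312 -> 19 windows
        rec = _rec(n=6500, fs=250.0)
        eps = [RhythmEpisode(0, 6500, "AFIB")]
        segs = segment_sliding(rec, [], eps, WindowingParams(2.5, 0.5),
                               label_dict, rhythm_task, "synth")
        assert len(segs) == 19
        assert all(s.samples.size == 625 for s in segs)

    def test_record_shorter_than_window_yields_nothing(self, label_dict, rhythm_task):
        rec = _rec(n=624, fs=250.0)
        segs = segment_sliding(rec, [], [RhythmEpisode(0, 624, "AFIB")],
                               WindowingParams(2.5, 0.5), label_dict, rhythm_task,
                               "synth")
        assert segs == []

    def test_zero_overlap_tiles_consecutively(self, label_dict, rhythm_task):
        rec = _rec(n=2500, fs=250.0)
        segs = segment_sliding(rec, [], [RhythmEpisode(0, 2500, "N")],
                               WindowingParams(2.5, 0.0), label_dict, rhythm_task,
                               "synth")
        assert [s.start for s in segs] == [0, 625, 1250, 1875]

    @given(st.integers(1, 5000), st.integers(1, 800), st.integers(1, 800))
    @settings(max_examples=200, deadline=None)
    def test_count_closed_form_matches_enumeration(self, L, w, s):
        assert window_count(L, w, s) == len(enumerate_windows(L, w, s))

    @pytest.mark.parametrize("task_name", ["form", "rhythm_reduced"])
    def test_oracle_equivalence_on_random_streams(self, task_name, label_dict):
        from ecgbench.annotations import builtin_task

        task = builtin_task(task_name)
        rng = np.random.default_rng(123)
        n_checked = 0
        for _ in range(150):
            L, beats, episodes = random_annotation_stream(rng)
            rec = EcgRecord("r", "p", np.zeros(L), 250.0, "II")
            counts = np.array([5, 3, 2])
            params = WindowingParams(2.5, 0.5)
            segs = segment_sliding(rec, beats, episodes, params, label_dict,
                                   task, "synth", class_counts=counts)
            got = {s.start: s.label for s in segs}
            w, stride = params.sizes(250.0)
            for start in enumerate_windows(L, w, stride):
                want = brute_force_window_label(
                    (start, start + w), beats, episodes, label_dict, task,
                    "synth", counts)
                if want == EXCLUDED:
                    assert start not in got
                else:
                    assert got[start] == want
                n_checked += 1
        assert n_checked > 500

    def test_stride_rounding_to_zero_rejected(self):
        with pytest.raises(ValueError):
            WindowingParams(0.001, 0.5).sizes(250.0)


class TestRecordingLevel:
    def test_recording_windows_inherit_label(self, label_dict, rhythm_task):
        rec = _rec(n=5000, fs=500.0)
        segs = segment_recording_windows(
            rec, RecordingLabel("r0", ("AFIB",)), WindowingParams(2.5, 0.5),
            label_dict, rhythm_task, "synth")
        # 10 s at 500 Hz, w=1250, s=625 -> 7 windows
        assert len(segs) == 7
        assert all(s.label == 0 for s in segs)

    def test_full_window_yields_exactly_one(self, label_dict, rhythm_task):
        rec = _rec(n=5000, fs=500.0)
        segs = segment_recording_windows(
            rec, RecordingLabel("r0", ("N",)), WindowingParams(10.0, 0.5),
            label_dict, rhythm_task, "synth")
        assert len(segs) == 1

    def test_unresolvable_label_skipped(self, label_dict, rhythm_task):
        rec = _rec(n=5000, fs=500.0)
        segs = segment_recording_windows(
            rec, RecordingLabel("r0", ("???",)), WindowingParams(2.5, 0.5),
            label_dict, rhythm_task, "synth")
        assert segs == []

    def test_whole_sequence_pads_and_crops(self, label_dict, rhythm_task):
        for n, expect_tail_zeros in ((4000, True), (5000, False), (30000, False)):
            rec = _rec(n=n, fs=500.0)
            seg = whole_sequence(rec, RecordingLabel("r0", ("AFIB",)), 10.0,
                                 label_dict, rhythm_task, "synth")
            assert seg.samples.size == 5000
            if expect_tail_zeros:
                assert np.all(seg.samples[4000:] == 0)


class TestAggregation:
    def test_majority(self):
        assert aggregate_predictions([("r", 0), ("r", 0), ("r", 1)]) == {"r": 0}

    def test_tie_goes_to_lowest_index(self):
        # verified against brute-force mode computation: both classes occur
        # once, the documented tie-break picks the lower index
        assert aggregate_predictions([("r", 1), ("r", 0)]) == {"r": 0}
        assert aggregate_predictions([("r", 2), ("r", 1)]) == {"r": 1}

    def test_single_window_is_its_own_label(self):
        assert aggregate_predictions([("r", 2)]) == {"r": 2}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_predictions([])


def test_segments_carry_provenance(beat_handle_small, label_dict, rhythm_task):
    from ecgbench.experiment import build_segments

    segs = build_segments(beat_handle_small, label_dict, rhythm_task, "windows2.5s")
    pids = {p for _, p in beat_handle_small.records}
    for s in segs:
        assert s.patient_id in pids
        assert s.record_id in beat_handle_small.record_ids
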