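import numpy as np
import pytest

from apnealite.preprocess import (
    APNEA,
    NORMAL,
    EventAnnotation,
    Recording,
    SegmentSet,
    load_segments,
    resample,
    save_segments,
    segment_event_scheme,
    segment_minute_scheme,
)


def minute_recording(n_minutes, fs=100.0, labels=None):
    n = int(n_minutes * 60 * fs)
    labels = labels if labels is not None else np.zeros(int(n_minutes), np.int8)
    return Recording(samples=np.arange(max(n, 1), dtype=np.float32), fs=fs,
                     modality="ecg", minute_labels=labels, record_id="m")


def event_recording(duration, events, fs=8.0, sleep_onset=0.0):
    return Recording(samples=np.zeros(int(duration * fs), np.float32), fs=fs,
                     modality="spo2", events=events, sleep_onset=sleep_onset,
                     record_id="e")


def brute_force_event_labels(events, duration, sleep_onset=0.0, grid_hz=16):
    """Per-sample oracle: mark a fine time grid apneic, count per window."""
    n = int(duration * grid_hz)
    apneic = np.zeros(n, bool)
    for e in events:
        a = int(np.round(e.onset * grid_hz))
        b = int(np.round(min(e.end, duration) * grid_hz))
        apneic[a:b] = True
    labels = []
    t0 = sleep_onset
    while t0 + 12.0 <= duration:
        a, b = int(round(t0 * grid_hz)), int(round((t0 + 12.0) * grid_hz))
        labels.append(APNEA if apneic[a:b].sum() >= 10.0 * grid_hz else NORMAL)
        t0 += 12.0
    return np.array(labels, np.int8)


class TestMinuteScheme:
    def test_ten_minutes_at_100hz(self):
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 0, 1, 0], np.int8)
        segs = segment_minute_scheme(minute_recording(10, labels=labels))
        assert segs.segments.shape == (10, 1200)
        np.testing.assert_array_equal(segs.labels, labels)

    def test_first_12s_of_each_minute_retained(self):
        segs = segment_minute_scheme(minute_recording(3))
        # samples are an arange, so row i must start at 60*i*fs
        for i in range(3):
            assert segs.segments[i, 0] == 60 * i * 100

    def test_sub_minute_recording_empty_with_warning(self):
        rec = Recording(samples=np.zeros(5900, np.float32), fs=100.0, modality="ecg",
                        minute_labels=np.array([0], np.int8))
        with pytest.warns(UserWarning, match="shorter than one minute"):
            segs = segment_minute_scheme(rec)
        assert len(segs) == 0

    def test_trailing_partial_minute_dropped(self):
        rec = Recording(samples=np.zeros(int(2.5 * 60 * 100), np.float32), fs=100.0,
                        modality="ecg", minute_labels=np.array([1, 0, 1], np.int8))
        assert len(segment_minute_scheme(rec)) == 2


class TestEventScheme:
    def test_event_covering_whole_window(self):
        segs = segment_event_scheme(event_recording(24, [EventAnnotation(0.0, 12.0)]))
        assert segs.labels[0] == APNEA
        assert segs.labels[1] == NORMAL

    def test_overlap_just_below_threshold_is_normal(self):
        # event overlaps the first window by 9.5 s
        segs = segment_event_scheme(event_recording(24, [EventAnnotation(2.5, 9.5)]))
        assert segs.labels[0] == NORMAL

    def test_overlap_exactly_ten_is_apnea(self):
        segs = segment_event_scheme(event_recording(24, [EventAnnotation(2.0, 10.0)]))
        assert segs.labels[0] == APNEA

    def test_union_of_short_events_reaches_threshold(self):
        events = [EventAnnotation(0.0, 5.0), EventAnnotation(6.0, 5.0)]
        assert segment_event_scheme(event_recording(12, events)).labels[0] == APNEA
        # single-event mode only sees 5 s at most
        assert segment_event_scheme(
            event_recording(12, events), overlap_mode="single").labels[0] == NORMAL

    def test_windows_anchored_at_sleep_onset(self):
        rec = event_recording(36, [EventAnnotation(10.0, 12.0)], sleep_onset=10.0)
        segs = segment_event_scheme(rec)
        assert segs.labels[0] == APNEA
        assert len(segs) == 2  # floor((36-10)/12)

    def test_event_past_end_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            segs = segment_event_scheme(event_recording(12, [EventAnnotation(1.0, 60.0)]))
        assert segs.labels[0] == APNEA

    def test_segment_count_formula(self):
        rec = event_recording(125, [EventAnnotation(0.0, 10.0)])
        assert len(segment_event_scheme(rec)) == 10  # floor(125/12)

    def test_matches_brute_force_oracle_on_random_layouts(self, rng):
        """Continuous-overlap labels equal per-sample counting, 60 layouts."""
        for _ in range(60):
            duration = float(rng.integers(60, 240))
            events = []
            t = 0.0
            while True:
                # 0.25-s grid keeps both routes exact in float arithmetic
                t += float(rng.integers(1, 60)) * 0.25
                dur = float(rng.integers(8, 80)) * 0.25
                if t + dur > duration:
                    break
                events.append(EventAnnotation(t, dur))
                t += dur
            rec = event_recording(duration, events)
            got = segment_event_scheme(rec).labels
            np.testing.assert_array_equal(got, brute_force_event_labels(events, duration))


class TestResample:
    def test_downsample_1536_to_1200(self, rng):
        seg = rng.normal(size=1536).astype(np.float32)
        assert resample(seg, 1200).shape == (1200,)

    def test_identity_when_lengths_match(self, rng):
        seg = rng.normal(size=96).astype(np.float32)
        np.testing.assert_array_equal(resample(seg, 96), seg)

    @pytest.mark.parametrize("method", ["poly", "linear"])
    def test_constant_preserved(self, method):
        seg = np.full(600, 97.0, np.float32)
        out = resample(seg, 96, method=method)
        # polyphase FIR passband ripple bounds the deviation; linear is exact
        np.testing.assert_allclose(out, 97.0, atol=0.01)

    def test_mean_preserved_for_bandlimited_input(self):
        t = np.linspace(0, 1, 600, endpoint=False)
        seg = (5 + np.sin(2 * np.pi * 3 * t)).astype(np.float32)
        out = resample(seg, 96)
        assert abs(out.mean() - seg.mean()) < 0.05

    def test_too_short_target_rejected(self):
        with pytest.raises(ValueError, match="n_target"):
            resample(np.zeros(10), 1)


class TestSegmentStore:
    def test_round_trip(self, tmp_path, rng):
        segs = SegmentSet(
            segments=rng.normal(size=(4, 96)).astype(np.float32),
            labels=np.array([0, 1, 1, 0], np.int8),
            fs=8.0,
            modality="spo2",
            source_ids=[f"r:{i}" for i in range(4)],
        )
        save_segments(segs, tmp_path / "store")
        back = load_segments(tmp_path / "store")
        np.testing.assert_allclose(back.segments, segs.segments, rtol=1e-4)
        np.testing.assert_array_equal(back.labels, segs.labels)
        assert back.source_ids == segs.source_ids
        assert back.modality == "spo2"


class TestValidation:
    def test_exactly_one_annotation_style(self):
        with pytest.raises(ValueError, match="exactly one"):
            Recording(samples=np.zeros(10), fs=1.0, modality="ecg")
        with pytest.raises(ValueError, match="exactly one"):
            Recording(samples=np.zeros(10), fs=1.0, modality="ecg",
                      minute_labels=np.zeros(1), events=[EventAnnotation(0, 1)])

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            EventAnnotation(-1.0, 5.0)
        with pytest.raises(ValueError):
            EventAnnotation(0.0, 0.0)
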