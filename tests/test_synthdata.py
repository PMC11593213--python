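
import numpy as np
import pytest

from apnealite.preprocess import (
    APNEA,
    EventAnnotation,
    segment_event_scheme,
    segment_minute_scheme,
)
from apnealite.synthdata import (
    SynthConfig,
    generate_events,
    make_recording_pair,
    read_dataset,
    read_record,
    synth_ecg,
    synth_spo2,
    write_dataset,
)


def cfg(**kwargs):
    base = dict(duration=600.0, seed=11)
    base.update(kwargs)
    return SynthConfig(**base)


class TestGenerateEvents:
    def test_zero_rate_empty(self):
        assert generate_events(cfg(event_rate=0.0, sub10_rate=0.0)) == []

    def test_nonoverlapping_sorted_with_minimum_gaps(self):
        events = generate_events(cfg(duration=3600.0, event_rate=40.0))
        assert events == sorted(events, key=lambda e: e.onset)
        for a, b in zip(events, events[1:]):
            assert b.onset - a.end >= 12.0 - 1e-9

    def test_deterministic_given_seed(self):
        assert generate_events(cfg()) == generate_events(cfg())

    def test_rate_realized(self):
        events = generate_events(cfg(duration=7200.0, event_rate=30.0, sub10_rate=0.0))
        assert len(events) == 60

    def test_infeasible_schedule_rejected(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_events(cfg(duration=600.0, event_rate=400.0))

    def test_durations_within_configured_ranges(self):
        events = generate_events(cfg(duration=3600.0))
        durs = np.array([e.duration for e in events])
        assert np.all((durs >= 3.0) & (durs <= 60.0))
        assert (durs >= 10.0).sum() >= len(durs) - int(round(4 * 1.0))  # sub-10 share


class TestSynthEcg:
    def test_sample_count(self):
        rec = synth_ecg([], cfg(duration=12.0, fs_ecg=100.0))
        assert rec.samples.shape == (1200,)
        assert rec.fs == 100.0

    def _r_peak_times(self, rec):
        x = rec.samples
        peaks = np.flatnonzero((x[1:-1] > 0.5) & (x[1:-1] >= x[:-2]) & (x[1:-1] > x[2:]))
        return (peaks + 1) / rec.fs

    def test_periodic_without_events_or_noise(self):
        rec = synth_ecg([], cfg(duration=60.0, noise_sd_ecg=0.0, hr_baseline=75.0))
        rr = np.diff(self._r_peak_times(rec))
        np.testing.assert_allclose(rr, 0.8, atol=0.011)  # one-sample jitter

    def test_rr_lengthens_during_events(self):
        events = [EventAnnotation(20.0, 20.0)]
        rec = synth_ecg(events, cfg(duration=60.0, noise_sd_ecg=0.0))
        t = self._r_peak_times(rec)
        rr = np.diff(t)
        mid = (t[:-1] + t[1:]) / 2
        inside = rr[(mid > 20.0) & (mid < 40.0)]
        outside = rr[mid < 20.0]
        assert inside.mean() > outside.mean() * 1.1

    def test_bad_heart_rate_rejected(self):
        with pytest.raises(ValueError):
            cfg(hr_baseline=0.0)


class TestSynthSpo2:
    def test_flat_near_baseline_without_events(self):
        c = cfg(duration=120.0)
        rec = synth_spo2([], c)
        dev = np.abs(rec.samples - c.spo2_baseline)
        assert abs(rec.samples.mean() - c.spo2_baseline) < 0.05
        assert (dev > 3 * c.noise_sd_spo2).mean() < 0.01  # Gaussian tail
        assert dev.max() < 6 * c.noise_sd_spo2

    def test_desaturation_reaches_four_percent(self):
        c = cfg(duration=120.0, noise_sd_spo2=0.0)
        rec = synth_spo2([EventAnnotation(30.0, 20.0)], c)
        assert rec.samples.min() <= c.spo2_baseline - 4.0 + 1e-5

    def test_sub10_activity_attenuated(self):
        c = cfg(duration=120.0, noise_sd_spo2=0.0)
        rec = synth_spo2([EventAnnotation(30.0, 5.0)], c)
        assert rec.samples.min() > c.spo2_baseline - 4.0

    def test_values_clipped_to_physical_range(self):
        c = cfg(duration=60.0, noise_sd_spo2=5.0, spo2_baseline=95.0)
        rec = synth_spo2([EventAnnotation(10.0, 30.0)], c)
        assert rec.samples.min() >= 0.0
        assert rec.samples.max() <= 100.0

    def test_quantization(self):
        c = cfg(duration=60.0, quantize_spo2=True)
        rec = synth_spo2([], c)
        np.testing.assert_array_equal(rec.samples, np.round(rec.samples))


class TestDeterminism:
    def test_identical_config_identical_recordings(self):
        a_ecg, a_spo2, a_ev = make_recording_pair(cfg())
        b_ecg, b_spo2, b_ev = make_recording_pair(cfg())
        np.testing.assert_array_equal(a_ecg.samples, b_ecg.samples)
        np.testing.assert_array_equal(a_spo2.samples, b_spo2.samples)
        assert a_ev == b_ev


class TestDatasetStore:
    def test_event_scheme_round_trip(self, tmp_path):
        ecg, spo2, events = make_recording_pair(cfg(), record_id="r0")
        write_dataset([ecg, spo2], "event", tmp_path)
        back = read_record(tmp_path, "r0", "ecg", "event")
        np.testing.assert_allclose(back.samples, ecg.samples, atol=1e-4)
        assert back.fs == ecg.fs
        assert len(back.events) == len(events)
        for a, b in zip(back.events, events):
            assert a.onset == pytest.approx(b.onset, abs=1e-5)
            assert a.duration == pytest.approx(b.duration, abs=1e-5)

    def test_minute_scheme_round_trip_and_labels(self, tmp_path):
        ecg, _, events = make_recording_pair(cfg(), record_id="r1")
        write_dataset([ecg], "minute", tmp_path)
        back = read_record(tmp_path, "r1", "ecg", "minute")
        assert back.minute_labels is not None
        assert len(back.minute_labels) == int(ecg.duration // 60)
        segs = segment_minute_scheme(back)
        assert len(segs) == len(back.minute_labels)

    def test_manifest_lists_all_records(self, tmp_path):
        ecg, spo2, _ = make_recording_pair(cfg(), record_id="r2")
        manifest = write_dataset([ecg, spo2], "event", tmp_path)
        assert len(manifest["records"]) == 2
        assert len(read_dataset(tmp_path)) == 2

    def test_empty_recording_list(self, tmp_path):
        manifest = write_dataset([], "event", tmp_path)
        assert manifest["records"] == []

    def test_segment_labels_match_generating_events(self, tmp_path):
        """Cross-module oracle: written events, re-read and windowed, give the
        labels the >= 10 s overlap rule dictates."""
        ecg, _, events = make_recording_pair(cfg(duration=1200.0), record_id="r3")
        write_dataset([ecg], "event", tmp_path)
        segs = segment_event_scheme(read_record(tmp_path, "r3", "ecg", "event"))
        from test_preprocess import brute_force_event_labels

        expected = brute_force_event_labels(events, ecg.duration, grid_hz=64)
        # re-read events are rounded to 1e-6 s; exact-boundary flips impossible
        np.testing.assert_array_equal(segs.labels, expected)
        assert segs.labels.sum() > 0


class TestLabelRecoverability:
    def test_apnea_prevalence_tracks_event_coverage(self):
        c = cfg(duration=3600.0, event_rate=30.0, sub10_rate=0.0)
        ecg, _, events = make_recording_pair(c)
        segs = segment_event_scheme(ecg)
        prevalence = segs.labels.mean()
        coverage = sum(e.duration for e in events) / c.duration
        # windows need >=10/12 coverage, so prevalence sits a bit below coverage
        assert 0.3 * coverage < prevalence < 1.2 * coverage


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(duration=0.0),
        dict(desat_depth=2.0),
        dict(spo2_baseline=70.0),
        dict(event_duration=(0.0, 5.0)),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cfg(**kwargs)
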