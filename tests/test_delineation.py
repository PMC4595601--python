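import numpy as np
import pytest

from drest.delineate import BeatSeries, clean_series, delineate, detect_beats
from drest.io import ECGRecord
from drest.synth import (SubjectProfile, generate_beat_series,
                         make_step_schedule, synthesize_waveform)


def _series(rr_ms, qt=400.0, tpe=90.0):
    t = 1.0 + np.cumsum(np.asarray(rr_ms)) / 1000.0
    n = len(t)
    rr = np.r_[np.nan, np.diff(t) * 1000.0]
    return BeatSeries(t, rr, np.full(n, qt), np.full(n, tpe), np.ones(n, bool))


class TestDetectBeats:
    def test_regular_rhythm_recovered(self, fixed_beats):
        rec = synthesize_waveform(fixed_beats)
        anchors = detect_beats(rec, "V3")
        assert len(anchors) == 60
        np.testing.assert_allclose(np.diff(anchors) * 1000.0, 1000.0, atol=3.0)

    def test_zero_signal_empty(self):
        rec = ECGRecord(180.0, ["V3"], np.zeros((1, 180 * 20)))
        with pytest.warns(UserWarning):
            assert len(detect_beats(rec, "V3")) == 0

    def test_alternating_rr_recovered(self):
        rr = np.tile([600.0, 1000.0], 30)
        s = _series(rr, qt=350.0, tpe=80.0)
        rec = synthesize_waveform(s)
        anchors = detect_beats(rec, "V3")
        assert len(anchors) == 60
        got = np.diff(anchors) * 1000.0
        np.testing.assert_allclose(got, rr[1:], atol=5.0)

    def test_short_record_rejected(self):
        rec = ECGRecord(180.0, ["V3"], np.zeros((1, 180 * 5)))
        with pytest.raises(ValueError):
            detect_beats(rec, "V3")


class TestDelineate:
    def test_known_intervals_recovered(self, fixed_beats):
        rec = synthesize_waveform(fixed_beats)
        series = delineate(rec, "V3", detect_beats(rec, "V3"))
        v = series.valid
        assert v.sum() >= 55
        assert np.nanmean(np.abs(series.qt_ms[v] - 400.0)) <= 10.0
        assert np.nanmean(np.abs(series.tpe_ms[v] - 90.0)) <= 10.0
        series.check()

    def test_noise_free_error_below_one_sample(self, fixed_beats):
        """Mean absolute QT/Tpe error within one sample interval at 180 Hz."""
        rec = synthesize_waveform(fixed_beats)
        series = delineate(rec, "V3", detect_beats(rec, "V3"))
        v = series.valid
        one_sample_ms = 1000.0 / rec.sampling_rate
        assert np.nanmean(np.abs(series.qt_ms[v] - 400.0)) <= one_sample_ms
        assert np.nanmean(np.abs(series.tpe_ms[v] - 90.0)) <= one_sample_ms

    def test_baseline_offset_invariance(self, fixed_beats):
        rec = synthesize_waveform(fixed_beats)
        anchors = detect_beats(rec, "V3")
        base = delineate(rec, "V3", anchors)
        shifted = ECGRecord(rec.sampling_rate, ["V3"], rec.signal + 0.4,
                            rec.start_time)
        off = delineate(shifted, "V3", detect_beats(shifted, "V3"))
        np.testing.assert_allclose(off.qt_ms[off.valid], base.qt_ms[base.valid],
                                   atol=1e-6)

    def test_clipped_last_beat_invalid(self, fixed_beats):
        rec = synthesize_waveform(fixed_beats)
        # cut the record 150 ms after the final R peak: no full T window
        n_keep = int((fixed_beats.t[-1] - rec.start_time + 0.15)
                     * rec.sampling_rate)
        clipped = ECGRecord(rec.sampling_rate, ["V3"],
                            rec.signal[:, :n_keep], rec.start_time)
        series = delineate(clipped, "V3", detect_beats(clipped, "V3"))
        assert not series.valid[-1]
        assert np.isnan(series.qt_ms[-1])

    def test_fewer_than_two_anchors_raises(self, fixed_beats):
        rec = synthesize_waveform(fixed_beats)
        with pytest.raises(ValueError):
            delineate(rec, "V3", np.array([5.0]))

    def test_valid_fraction_under_noise(self):
        rng = np.random.default_rng(11)
        p = SubjectProfile(noise_sd_ms=0.0, rr_mean_ms=900.0,
                           rr_step_schedule=make_step_schedule(rng, 180, 900),
                           seed=5)
        gen = generate_beat_series(p, 180.0)
        rec = synthesize_waveform(gen.series, noise_sd_mv=0.05,
                                  rng=np.random.default_rng(12))
        series = delineate(rec, "V3", detect_beats(rec, "V3"))
        assert series.valid.mean() >= 0.95


class TestCleanSeries:
    def test_clean_input_is_noop(self, fixed_beats):
        out = clean_series(fixed_beats)
        np.testing.assert_array_equal(out.valid, fixed_beats.valid)

    def test_single_outlier_invalidated(self, fixed_beats):
        rng = np.random.default_rng(0)
        qt = 400.0 + rng.normal(0, 5.0, len(fixed_beats))
        s = BeatSeries(fixed_beats.t, fixed_beats.rr_ms, qt,
                       fixed_beats.tpe_ms, fixed_beats.valid)
        s.qt_ms[30] = 900.0
        out = clean_series(s)
        assert not out.valid[30]
        assert out.valid.sum() == len(s) - 1

    def test_short_series_unchanged_with_warning(self):
        s = _series([800.0, 800.0, 800.0])
        with pytest.warns(UserWarning):
            out = clean_series(s)
        np.testing.assert_array_equal(out.valid, s.valid)

    def test_implausible_rr_flagged(self, fixed_beats):
        s = BeatSeries(fixed_beats.t, fixed_beats.rr_ms.copy(),
                       fixed_beats.qt_ms, fixed_beats.tpe_ms,
                       fixed_beats.valid)
        s.rr_ms[10] = 2900.0
        out = clean_series(s)
        assert not out.valid[10]


def test_beat_series_invariants_enforced():
    with pytest.raises(ValueError):
        BeatSeries(np.array([1.0, 1.0]), np.array([np.nan, 0.0]),
                   np.zeros(2), np.zeros(2), np.zeros(2, bool))
    s = _series([800.0] * 5)
    s.tpe_ms[2] = 500.0  # Tpe must stay below QT on valid beats
    with pytest.raises(ValueError):
        s.check()
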