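"""Envelope computation, thresholding, and spindle event detection."""
import numpy as np
import pytest

from swacomp.io_edf import EegRecording, Hypnogram
from swacomp.preprocess import SampleMask
from swacomp.spindles import (SpindleEvent, detect_spindles, moving_rms,
                              reject_envelope_outliers, spindle_threshold,
                              upper_envelope)
from swacomp.synthetic import score_detection

FS = 128.0


def _analytic_magnitude_oracle(x):
    """Independent analytic-signal magnitude via explicit one-sided FFT."""
    n = x.size
    X = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1
    if n % 2 == 0:
        h[n // 2] = 1
        h[1:n // 2] = 2
    else:
        h[1:(n + 1) // 2] = 2
    return np.abs(np.fft.ifft(X * h))


class TestUpperEnvelope:
    def test_constant_amplitude_sine(self):
        t = np.arange(int(20 * FS)) / FS
        env = upper_envelope(20.0 * np.sin(2 * np.pi * 12.0 * t))
        core = env[int(2 * FS):-int(2 * FS)]
        assert np.all(np.abs(core - 20.0) < 0.05 * 20.0)

    def test_zero_signal_zero_envelope(self):
        assert np.allclose(upper_envelope(np.zeros(1000)), 0)

    def test_modulated_sine_tracks_modulator(self):
        t = np.arange(int(20 * FS)) / FS
        mod = 0.5 * (1 + np.cos(2 * np.pi * 0.5 * t))   # raised cosine
        x = 10.0 * mod * np.sin(2 * np.pi * 12.0 * t)
        env = upper_envelope(x)
        oracle = _analytic_magnitude_oracle(x)
        assert np.allclose(env, oracle, atol=1e-8)
        sl = slice(int(2 * FS), -int(2 * FS))
        rms_err = np.sqrt(np.mean((env[sl] - 10 * mod[sl]) ** 2))
        assert rms_err < 0.05 * np.sqrt(np.mean((10 * mod[sl]) ** 2))


class TestSpindleThreshold:
    def test_constant_envelope_returns_it(self):
        env = np.full(int(60 * FS), 7.0)
        thr = spindle_threshold(env, SampleMask(length=env.size), FS)
        assert np.isclose(thr, 7.0)

    def test_block_envelope_matches_sort_oracle(self):
        n = int(400 * FS)
        env = np.ones(n)
        env[3 * n // 4:] = 10.0                       # long blocks
        mask = SampleMask(length=n)
        thr = spindle_threshold(env, mask, FS)
        oracle = float(np.percentile(moving_rms(env, FS), 75,
                                     method="linear"))
        assert 1.0 < thr < 10.0
        assert np.isclose(thr, oracle)

    def test_homogeneous_in_scale(self):
        rng = np.random.default_rng(0)
        env = np.abs(rng.normal(0, 3, int(120 * FS)))
        mask = SampleMask(length=env.size)
        t1 = spindle_threshold(env, mask, FS)
        t2 = spindle_threshold(4.0 * env, mask, FS)
        assert np.isclose(t2, 4.0 * t1)

    def test_masked_samples_never_enter_threshold(self):
        n = int(120 * FS)
        env = np.ones(n)
        env[:n // 2] = 100.0
        excl = SampleMask(length=n, excluded=[(0, n // 2)])
        thr = spindle_threshold(env, excl, FS)
        assert thr < 2.0        # the 100 µV half was masked out

    def test_empty_analyzable_raises(self):
        m = SampleMask(length=100, excluded=[(0, 100)])
        with pytest.raises(ValueError):
            spindle_threshold(np.ones(100), m, FS)


from conftest import make_probe_recording as _burst_recording  # noqa: E402


class TestDetectSpindles:
    def test_injected_12hz_burst_found_as_late_fast_only(self):
        rec, hyp = _burst_recording(12.0)
        lf = detect_spindles(rec, hyp, "late_fast")
        hits = [e for e in lf if e.t_onset_s < 101.0 and e.t_offset_s > 100.0]
        assert len(hits) == 1
        assert not any(e.t_onset_s < 101.0 and e.t_offset_s > 100.0
                       for e in detect_spindles(rec, hyp, "early_fast"))

    def test_injected_16hz_burst_is_early_fast_only(self):
        rec, hyp = _burst_recording(16.0)
        ef = detect_spindles(rec, hyp, "early_fast")
        assert any(e.t_onset_s < 101.0 and e.t_offset_s > 100.0 for e in ef)
        assert not any(e.t_onset_s < 101.0 and e.t_offset_s > 100.0
                       for e in detect_spindles(rec, hyp, "late_fast"))

    def test_14hz_burst_in_neither_band(self):
        # moderate amplitude: brief 14 Hz bursts spread spectral energy into
        # both passbands, so the exclusion only holds below the threshold
        rec, hyp = _burst_recording(14.0, amp=10.0)
        for band in ("late_fast", "early_fast"):
            assert not any(e.t_onset_s < 101.0 and e.t_offset_s > 100.0
                           for e in detect_spindles(rec, hyp, band))

    def test_too_short_burst_rejected(self):
        rec, hyp = _burst_recording(12.0, dur_s=0.3)
        assert not any(e.t_onset_s < 101.0 and e.t_offset_s > 100.0
                       for e in detect_spindles(rec, hyp, "late_fast"))

    def test_over_range_burst_rejected_as_artifact(self):
        # 60 µV peak-to-peak well exceeds the 40 µV range ceiling
        rec, hyp = _burst_recording(12.0, amp=30.0)
        assert not any(e.t_onset_s < 101.0 and e.t_offset_s > 100.0
                       for e in detect_spindles(rec, hyp, "late_fast"))

    def test_events_never_overlap_within_band(self, detected_night):
        for key in ("lf", "ef"):
            evs = sorted(detected_night[key], key=lambda e: e.t_onset_s)
            for a, b in zip(evs, evs[1:]):
                assert a.t_offset_s <= b.t_onset_s

    def test_every_event_satisfies_invariants(self, detected_night):
        for key in ("lf", "ef"):
            assert detected_night[key]
            for e in detected_night[key]:
                e.validate()

    def test_recall_precision_on_synthetic_night(self, detected_night):
        truth = detected_night["truth"]
        for key, band in (("lf", "late_fast"), ("ef", "early_fast")):
            det = [(e.t_onset_s + e.t_offset_s) / 2
                   for e in detected_night[key]]
            tru = [t + d / 2 for t, d, b, a in truth.spindles if b == band]
            precision, recall, _ = score_detection(det, tru, 0.5)
            assert recall >= 0.9, band
            assert precision >= 0.9, band


def test_8sd_peak_outlier_removed():
    # the rejection rule computes mean/SD over the contaminated population,
    # so the population must be large enough that one 10-SD point cannot
    # inflate the spread below the 8-SD boundary
    rng = np.random.default_rng(5)
    events = [SpindleEvent("late_fast", float(i), float(i) + 1.0, 1.0,
                           peak_envelope_uv=float(p), range_uv=20.0,
                           t_peak_env_s=float(i) + 0.5)
              for i, p in enumerate(rng.normal(12, 0.5, 400))]
    peaks = np.array([e.peak_envelope_uv for e in events])
    outlier = SpindleEvent("late_fast", 999.0, 1000.0, 1.0,
                           peak_envelope_uv=float(peaks.mean()
                                                  + 10 * peaks.std()),
                           range_uv=20.0, t_peak_env_s=999.5)
    kept = reject_envelope_outliers(events + [outlier])
    assert outlier not in kept and kept == events
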