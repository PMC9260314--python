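"""Detrending, artifact masking, stage masking, and band-pass behavior."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swacomp.io_edf import Hypnogram
from swacomp.preprocess import (SLOW_BAND, SLOW_ORDER, SPINDLE_BANDS,
                                SPINDLE_ORDER, SampleMask, bandpass_slow,
                                bandpass_spindle, butterworth_gain,
                                combine_masks, high_amplitude_mask,
                                sliding_detrend)

FS = 128.0


def _measured_gain(filtered, amplitude=1.0):
    """Peak amplitude in the central half (edge transients excluded)."""
    n = filtered.size
    return np.abs(filtered[n // 4: 3 * n // 4]).max() / amplitude


class TestSlidingDetrend:
    def test_constant_removed(self):
        out = sliding_detrend(np.full(int(60 * FS), 50.0), FS)
        assert np.abs(out).max() < 1e-9

    def test_linear_ramp_removed(self):
        x = np.linspace(0, 1000, int(60 * FS))
        out = sliding_detrend(x, FS)
        assert np.abs(out).max() < 1e-6 * np.abs(x).max()

    def test_oscillation_preserved_and_matches_moving_mean_oracle(self):
        t = np.arange(int(60 * 100)) / 100
        x = np.sin(2 * np.pi * 1.0 * t)
        out = sliding_detrend(x, 100.0, window_s=3.0)
        # independent oracle: centered local-linear fit per sample reduces to
        # the window mean at the window center (interior samples only)
        win = 301
        half = win // 2
        csum = np.concatenate([[0.0], np.cumsum(x)])
        interior = np.arange(half, x.size - half)
        mov_mean = (csum[interior + half + 1] - csum[interior - half]) / win
        assert np.allclose(out[interior], x[interior] - mov_mean, atol=1e-9)
        err = out[interior] - x[interior]
        rms_err = np.sqrt(np.mean(err ** 2) / np.mean(x[interior] ** 2))
        assert rms_err < 0.05

    def test_window_longer_than_signal_raises(self):
        with pytest.raises(ValueError):
            sliding_detrend(np.zeros(10), FS, window_s=3.0)


class TestHighAmplitudeMask:
    def test_clean_data_empty_mask(self):
        m = high_amplitude_mask(np.random.default_rng(0).normal(0, 30, 12800),
                                FS)
        assert m.excluded == []

    def test_spike_excludes_its_window(self):
        x = np.zeros(int(30 * FS))
        x[int(10 * FS)] = 1000.0
        m = high_amplitude_mask(x, FS)
        win = int(3 * FS)
        start = (int(10 * FS) // win) * win
        assert m.excluded == [(start, start + win)]

    def test_exactly_900_not_excluded(self):
        x = np.zeros(int(12 * FS))
        x[100] = 900.0
        assert high_amplitude_mask(x, FS).excluded == []


class TestCombineMasks:
    def test_all_n3_no_artifact_keeps_everything(self):
        hyp = Hypnogram(30, ("N3",) * 4)
        art = SampleMask(length=int(120 * FS))
        m = combine_masks(art, hyp, FS)
        assert m.n_excluded == 0

    def test_all_wake_excludes_everything(self):
        hyp = Hypnogram(30, ("W",) * 4)
        art = SampleMask(length=int(120 * FS))
        m = combine_masks(art, hyp, FS)
        assert m.n_excluded == m.length

    def test_alternating_n2_rem_excludes_the_rem_epochs(self):
        hyp = Hypnogram(30, ("N2", "REM") * 3)
        n = int(180 * FS)
        m = combine_masks(SampleMask(length=n), hyp, FS)
        ok = m.analyzable_boolean()
        spe = int(30 * FS)
        for e in range(6):
            expected = (e % 2 == 0)
            assert ok[e * spe:(e + 1) * spe].all() == expected

    def test_length_mismatch_raises(self):
        a = SampleMask(length=10)
        b = SampleMask(length=20)
        with pytest.raises(ValueError):
            a.union(b)


class TestBandpass:
    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass_slow(np.zeros(1000), 200.0), 0)

    @pytest.mark.parametrize("freq,lo,hi", [
        (1.0, 0.95, 1.0 + 1e-3),   # passband center (tiny numerical excess)
        (20.0, 0.0, 0.01),         # stopband
    ])
    def test_slow_band_gain_matches_response_oracle(self, freq, lo, hi):
        t = np.arange(int(60 * 200)) / 200
        out = bandpass_slow(np.sin(2 * np.pi * freq * t), 200.0)
        g = _measured_gain(out)
        assert lo <= g <= hi
        predicted = butterworth_gain(SLOW_ORDER, *SLOW_BAND, 200.0, freq)
        assert abs(g - predicted) < 0.02

    @pytest.mark.parametrize("freq,band,lo,hi", [
        (12.0, "late_fast", 0.9, 1.0),
        (12.0, "early_fast", 0.0, 0.1),
        (16.0, "early_fast", 0.9, 1.0),
        (16.0, "late_fast", 0.0, 0.1),
    ])
    def test_spindle_band_selectivity(self, freq, band, lo, hi):
        t = np.arange(int(30 * FS)) / FS
        out = bandpass_spindle(np.sin(2 * np.pi * freq * t), FS, band)
        g = _measured_gain(out)
        assert lo <= g <= hi
        predicted = butterworth_gain(SPINDLE_ORDER, *SPINDLE_BANDS[band],
                                     FS, freq)
        assert abs(g - predicted) < 0.05

    def test_14hz_attenuated_in_both_bands(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 14.0 * t)
        for band, center in (("late_fast", 12.0), ("early_fast", 16.0)):
            g14 = _measured_gain(bandpass_spindle(x, FS, band))
            gc = _measured_gain(bandpass_spindle(
                np.sin(2 * np.pi * center * t), FS, band))
            assert g14 < 0.75 * gc

    def test_zero_phase_no_lag(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        y = bandpass_slow(x, FS)
        sl = slice(int(5 * FS), int(25 * FS))
        lags = range(-3, 4)
        corr = [np.dot(x[sl], np.roll(y, k)[sl]) for k in lags]
        assert abs(list(lags)[int(np.argmax(corr))]) <= 1

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 4000), rng.normal(0, 1, 4000)
        lhs = bandpass_slow(2.0 * x + 3.0 * y, FS)
        rhs = 2.0 * bandpass_slow(x, FS) + 3.0 * bandpass_slow(y, FS)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_band_edge_at_nyquist_raises(self):
        with pytest.raises(ValueError):
            bandpass_spindle(np.zeros(100), 30.0, "early_fast")


class TestSampleMaskProperties:
    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 100), st.integers(0, 100)),
                    max_size=8))
    def test_normalization_sorts_merges_and_clips(self, raw):
        m = SampleMask(length=100, excluded=[(min(a, b), max(a, b))
                                             for a, b in raw])
        for (lo, hi), (lo2, _) in zip(m.excluded, m.excluded[1:]):
            assert hi < lo2            # disjoint and sorted
        assert all(0 <= lo < hi <= 100 for lo, hi in m.excluded)
        # boolean round trip
        assert SampleMask.from_boolean(m.excluded_boolean()).excluded \
            == m.excluded
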