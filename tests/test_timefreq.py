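"""Peri-event segmentation, Morlet maps, normalization, and ROI power."""
import numpy as np
import pytest

from swacomp.slow_waves import SlowWaveEvent
from swacomp.timefreq import (RoiSpec, TimeFrequencyMap, baseline_segments,
                              default_freqs, morlet_tfr, normalize_and_average,
                              peri_event_segments, roi_power)

FS = 128.0


def _ev(t):
    return SlowWaveEvent(t_down_zc_s=t - 0.4, t_trough_s=t, trough_uv=-80.0,
                         t_up_zc_s=t + 0.3, t_peak_s=t + 0.6, peak_uv=40.0,
                         t_end_zc_s=t + 0.8, duration_s=1.2, stage="N3")


class TestSegments:
    def test_segment_covers_five_seconds_centered_on_trough(self):
        x = np.arange(int(20 * FS), dtype=float)
        segs, kept, dropped = peri_event_segments(x, FS, [_ev(10.0)])
        assert dropped == 0 and len(segs) == 1
        assert segs[0].size == int(5 * FS)
        assert segs[0][0] == int(7.5 * FS)     # starts at t = 7.5 s

    def test_edge_event_dropped_and_counted(self):
        x = np.zeros(int(20 * FS))
        segs, kept, dropped = peri_event_segments(x, FS, [_ev(1.0), _ev(10.0)])
        assert dropped == 1 and len(segs) == 1 and kept == [_ev(10.0)]

    def test_all_valid_events_give_that_many_segments(self):
        x = np.zeros(int(120 * FS))
        events = [_ev(t) for t in (10.0, 30.0, 50.0, 70.0)]
        segs, kept, dropped = peri_event_segments(x, FS, events)
        assert len(segs) == len(events) and dropped == 0

    def test_baseline_immediately_precedes_peri_segment(self):
        x = np.arange(int(40 * FS), dtype=float)
        bases = baseline_segments(x, FS, [_ev(20.0)], [_ev(20.0)])
        assert len(bases) == 1
        assert bases[0][0] == int(12.5 * FS)   # [12.5, 17.5) s
        assert bases[0].size == int(5 * FS)

    def test_baseline_containing_another_trough_discarded(self):
        x = np.zeros(int(40 * FS))
        bases = baseline_segments(x, FS, [_ev(20.0)], [_ev(20.0), _ev(15.0)])
        assert bases == []

    def test_baseline_out_of_range_dropped(self):
        x = np.zeros(int(40 * FS))
        assert baseline_segments(x, FS, [_ev(3.0)], [_ev(3.0)]) == []


class TestMorlet:
    def test_frequency_axis_has_65_rows(self):
        assert default_freqs().size == 65
        m = morlet_tfr(np.zeros(int(5 * FS)), FS)
        assert m.values.shape[0] == 65

    @pytest.mark.parametrize("tone", [6.0, 12.0, 16.0])
    def test_pure_tone_peaks_at_its_own_row(self, tone):
        t = np.arange(int(5 * FS)) / FS
        m = morlet_tfr(np.sin(2 * np.pi * tone * t), FS)
        peak_row = m.freqs_hz[np.argmax(m.values.mean(axis=1))]
        assert abs(peak_row - tone) <= 0.25

    def test_zero_segment_gives_zero_map(self):
        m = morlet_tfr(np.zeros(int(5 * FS)), FS)
        assert np.all(m.values == 0)

    def test_time_axis_symmetric_about_zero(self):
        m = morlet_tfr(np.zeros(int(5 * FS)), FS)
        assert np.allclose(m.times_s, -m.times_s[::-1])


def _random_map(rng, low=0.5, high=2.0):
    freqs = default_freqs()
    times = (np.arange(64) - 31.5) / FS
    return TimeFrequencyMap(freqs, times,
                            rng.uniform(low, high, (freqs.size, times.size)))


class TestNormalizeAndRoi:
    def test_self_normalization_is_one(self):
        rng = np.random.default_rng(0)
        m = _random_map(rng)
        flat = TimeFrequencyMap(m.freqs_hz, m.times_s,
                                np.tile(m.values.mean(axis=1)[:, None],
                                        (1, m.times_s.size)))
        out = normalize_and_average([flat], [flat])
        assert np.allclose(out.values, 1.0)

    def test_events_twice_baselines_gives_two(self):
        rng = np.random.default_rng(1)
        base = _random_map(rng)
        flat = TimeFrequencyMap(base.freqs_hz, base.times_s,
                                np.tile(base.values.mean(axis=1)[:, None],
                                        (1, base.times_s.size)))
        ev = TimeFrequencyMap(flat.freqs_hz, flat.times_s, 2 * flat.values)
        out = normalize_and_average([ev], [flat])
        assert np.allclose(out.values, 2.0)

    def test_matches_direct_two_loop_oracle(self):
        rng = np.random.default_rng(2)
        evs = [_random_map(rng) for _ in range(3)]
        bases = [_random_map(rng) for _ in range(4)]
        out = normalize_and_average(evs, bases)
        nf, nt = out.values.shape
        for fi in range(0, nf, 16):
            base_mean = np.mean([b.values[fi, ti] for b in bases
                                 for ti in range(nt)])
            for ti in range(0, nt, 16):
                ev_mean = np.mean([e.values[fi, ti] for e in evs])
                assert np.isclose(out.values[fi, ti], ev_mean / base_mean)

    def test_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(3)
        evs = [_random_map(rng) for _ in range(2)]
        bases = [_random_map(rng) for _ in range(2)]
        out1 = normalize_and_average(evs, bases)
        scale = 7.3
        evs2 = [TimeFrequencyMap(m.freqs_hz, m.times_s, scale * m.values)
                for m in evs]
        bases2 = [TimeFrequencyMap(m.freqs_hz, m.times_s, scale * m.values)
                  for m in bases]
        out2 = normalize_and_average(evs2, bases2)
        assert np.allclose(out1.values, out2.values)

    def test_zero_baseline_raises(self):
        rng = np.random.default_rng(4)
        m = _random_map(rng)
        zero = TimeFrequencyMap(m.freqs_hz, m.times_s,
                                np.zeros_like(m.values))
        with pytest.raises(ZeroDivisionError):
            normalize_and_average([m], [zero])

    def test_roi_of_uniform_map_is_its_value(self):
        freqs = default_freqs()
        times = (np.arange(64) - 31.5) / FS
        m = TimeFrequencyMap(freqs, times, np.full((freqs.size, times.size),
                                                   3.5))
        roi = RoiSpec("r", 10.0, 13.5, -0.1, 0.1)
        assert np.isclose(roi_power(m, roi), 3.5)

    def test_single_cell_roi_returns_that_cell(self):
        rng = np.random.default_rng(5)
        m = _random_map(rng)
        fi, ti = 10, 20
        eps = 1e-4
        roi = RoiSpec("c", m.freqs_hz[fi] - eps, m.freqs_hz[fi] + eps,
                      m.times_s[ti] - eps, m.times_s[ti] + eps)
        assert np.isclose(roi_power(m, roi), m.values[fi, ti])

    def test_checkerboard_matches_direct_summation_oracle(self):
        freqs = default_freqs()
        times = (np.arange(64) - 31.5) / FS
        vals = np.indices((freqs.size, times.size)).sum(axis=0) % 2 * 1.0
        m = TimeFrequencyMap(freqs, times, vals)
        roi = RoiSpec("cb", 5.0, 9.0, -0.2, 0.3)
        fsel = (freqs >= 5.0 - 1e-9) & (freqs <= 9.0 + 1e-9)
        tsel = (times >= -0.2 - 1e-9) & (times <= 0.3 + 1e-9)
        total, count = 0.0, 0
        for fi in np.flatnonzero(fsel):
            for ti in np.flatnonzero(tsel):
                total += vals[fi, ti]
                count += 1
        assert np.isclose(roi_power(m, roi), total / count)

    def test_roi_outside_grid_raises(self):
        rng = np.random.default_rng(6)
        m = _random_map(rng)
        with pytest.raises(ValueError):
            roi_power(m, RoiSpec("x", 21.0, 25.0, -0.1, 0.1))
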