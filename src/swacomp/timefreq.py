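"""Peri-trough Morlet time-frequency maps and baseline-normalized ROI power.

Each slow-wave trough is centered in a 5-s segment of the unfiltered EEG and
matched to the 5-s baseline immediately preceding the segment (discarded if
it contains any slow-wave trough).  An 8-cycle Morlet transform between 4
and 20 Hz in 0.25 Hz steps yields amplitude maps; event maps are averaged
and divided, per frequency, by the baseline mean over time and events.  ROI
power is the mean normalized amplitude over a frequency × time rectangle.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .slow_waves import SlowWaveEvent

FREQ_LO_HZ = 4.0
FREQ_HI_HZ = 20.0
FREQ_STEP_HZ = 0.25
N_CYCLES = 8
HALF_WIDTH_S = 2.5

#: ROI rectangles used for subtype power summaries.  These mirror the
#: detection bands crossed with the coupling window; any replication against
#: previously published ROI magnitudes must set the rectangles explicitly.
DEFAULT_ROIS = {
    "late_fast": dict(f_lo_hz=10.0, f_hi_hz=13.5, t_lo_s=0.2, t_hi_s=1.5),
    "early_fast": dict(f_lo_hz=14.5, f_hi_hz=18.0, t_lo_s=0.2, t_hi_s=1.5),
}


def default_freqs() -> np.ndarray:
    n = int(round((FREQ_HI_HZ - FREQ_LO_HZ) / FREQ_STEP_HZ)) + 1
    return FREQ_LO_HZ + FREQ_STEP_HZ * np.arange(n)


@dataclass
class TimeFrequencyMap:
    freqs_hz: np.ndarray
    times_s: np.ndarray
    values: np.ndarray          # [frequency][time] amplitude

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.freqs_hz.size, self.times_s.size):
            raise ValueError("values must be [n_freqs, n_times]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time-frequency values must be finite")


@dataclass
class RoiSpec:
    name: str
    f_lo_hz: float
    f_hi_hz: float
    t_lo_s: float
    t_hi_s: float

    def __post_init__(self) -> None:
        if not self.f_lo_hz < self.f_hi_hz:
            raise ValueError("require f_lo < f_hi")
        if not self.t_lo_s < self.t_hi_s:
            raise ValueError("require t_lo < t_hi")


def peri_event_segments(signal: np.ndarray, sampling_rate_hz: float,
                        events: Sequence[SlowWaveEvent],
                        half_width_s: float = HALF_WIDTH_S,
                        ) -> tuple[list[np.ndarray], list[SlowWaveEvent], int]:
    """5-s segments centered on troughs; edge events are dropped and counted."""
    x = np.asarray(signal, dtype=np.float64)
    hw = int(round(half_width_s * sampling_rate_hz))
    segments, kept, dropped = [], [], 0
    for ev in events:
        c = int(round(ev.t_trough_s * sampling_rate_hz))
        lo, hi = c - hw, c + hw
        if lo < 0 or hi > x.size:
            dropped += 1
            continue
        segments.append(x[lo:hi])
        kept.append(ev)
    return segments, kept, dropped


def baseline_segments(signal: np.ndarray, sampling_rate_hz: float,
                      events: Sequence[SlowWaveEvent],
                      all_slow_waves: Sequence[SlowWaveEvent],
                      half_width_s: float = HALF_WIDTH_S) -> list[np.ndarray]:
    """5-s baselines ending where each event's peri-segment begins.

    A baseline containing any slow-wave trough (from the full detected set)
    is discarded, as is one that starts before the recording.
    """
    x = np.asarray(signal, dtype=np.float64)
    fs = sampling_rate_hz
    hw = int(round(half_width_s * fs))
    troughs = np.sort([e.t_trough_s for e in all_slow_waves])
    out = []
    for ev in events:
        c = int(round(ev.t_trough_s * fs))
        lo, hi = c - 3 * hw, c - hw
        if lo < 0:
            continue
        t_lo, t_hi = lo / fs, hi / fs
        i = np.searchsorted(troughs, t_lo, side="left")
        if i < troughs.size and troughs[i] < t_hi:
            continue
        out.append(x[lo:hi])
    return out


def morlet_tfr(segment: np.ndarray, sampling_rate_hz: float,
               n_cycles: float = N_CYCLES,
               freqs_hz: np.ndarray | None = None) -> TimeFrequencyMap:
    """Morlet amplitude map of one segment (wrapper over a batch of one)."""
    return morlet_tfr_batch([segment], sampling_rate_hz, n_cycles, freqs_hz)[0]


def morlet_tfr_batch(segments: Sequence[np.ndarray], sampling_rate_hz: float,
                     n_cycles: float = N_CYCLES,
                     freqs_hz: np.ndarray | None = None,
                     ) -> list[TimeFrequencyMap]:
    """Morlet amplitude maps for equally long segments in one pass."""
    from mne.time_frequency import tfr_array_morlet

    freqs = default_freqs() if freqs_hz is None else np.asarray(freqs_hz)
    data = np.stack([np.asarray(s, dtype=np.float64) for s in segments])
    if data.ndim != 2:
        raise ValueError("segments must be equal-length 1-D arrays")
    n_times = data.shape[1]
    if sampling_rate_hz <= 2 * freqs.max():
        raise ValueError("sampling rate too low for the requested frequencies")
    out = tfr_array_morlet(data[:, None, :], sfreq=sampling_rate_hz,
                           freqs=freqs, n_cycles=n_cycles, output="complex",
                           zero_mean=True, verbose="error")
    amp = np.abs(out[:, 0])                      # [epoch][freq][time]
    times = (np.arange(n_times) - (n_times - 1) / 2) / sampling_rate_hz
    return [TimeFrequencyMap(freqs, times, a) for a in amp]


def normalize_and_average(event_maps: Sequence[TimeFrequencyMap],
                          baseline_maps: Sequence[TimeFrequencyMap],
                          ) -> TimeFrequencyMap:
    """Mean event map divided, per frequency, by the baseline grand mean."""
    if len(event_maps) == 0 or len(baseline_maps) == 0:
        raise ValueError("need at least one event map and one baseline map")
    ev = np.mean([m.values for m in event_maps], axis=0)
    base = np.mean([m.values.mean(axis=1) for m in baseline_maps], axis=0)
    if np.any(base == 0):
        raise ZeroDivisionError("zero baseline mean at some frequency")
    ref = event_maps[0]
    return TimeFrequencyMap(ref.freqs_hz, ref.times_s, ev / base[:, None])


def roi_power(tf_map: TimeFrequencyMap, roi: RoiSpec) -> float:
    """Mean map value over all grid cells inside the ROI (inclusive bounds)."""
    frow = ((tf_map.freqs_hz >= roi.f_lo_hz - 1e-9)
            & (tf_map.freqs_hz <= roi.f_hi_hz + 1e-9))
    tcol = ((tf_map.times_s >= roi.t_lo_s - 1e-9)
            & (tf_map.times_s <= roi.t_hi_s + 1e-9))
    if not frow.any() or not tcol.any():
        raise ValueError("ROI lies outside the map grid")
    return float(tf_map.values[np.ix_(frow, tcol)].mean())
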