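"""Detrending, gross-artifact masking and the zero-phase band-pass filters.

The two detector front-ends are a 6th-order 0.16–4 Hz Butterworth for the
slow-wave band and 3rd-order Butterworths for the two spindle bands
(10–13.5 Hz "late-fast", 14.5–18 Hz "early-fast"); all are applied
forward-backward (zero phase) in second-order sections.  The 13.5–14.5 Hz
gap is deliberately outside both spindle passbands: spindle subtypes share
frequency content near 14 Hz and events there are not classifiable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

import numpy as np
from scipy import signal as sps

from .io_edf import Hypnogram

SLOW_BAND = (0.16, 4.0)
SLOW_ORDER = 6
SPINDLE_BANDS: dict[str, tuple[float, float]] = {
    "late_fast": (10.0, 13.5),
    "early_fast": (14.5, 18.0),
}
SPINDLE_ORDER = 3


@dataclass
class SampleMask:
    """Excluded sample ranges (half-open, 0-based) over a recording."""

    length: int
    excluded: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.excluded = self._normalize(self.excluded)

    def _normalize(self, ranges) -> list[tuple[int, int]]:
        clipped = []
        for lo, hi in ranges:
            lo, hi = max(0, int(lo)), min(self.length, int(hi))
            if hi > lo:
                clipped.append((lo, hi))
        clipped.sort()
        merged: list[tuple[int, int]] = []
        for lo, hi in clipped:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        return merged

    @classmethod
    def from_boolean(cls, excluded: np.ndarray) -> "SampleMask":
        """Build from a boolean array with True marking excluded samples."""
        excluded = np.asarray(excluded, dtype=bool)
        if excluded.size == 0:
            return cls(length=0)
        edges = np.flatnonzero(np.diff(excluded.astype(np.int8)))
        starts = list(edges[excluded[edges + 1]] + 1)
        stops = list(edges[~excluded[edges + 1]] + 1)
        if excluded[0]:
            starts.insert(0, 0)
        if excluded[-1]:
            stops.append(excluded.size)
        return cls(length=excluded.size, excluded=list(zip(starts, stops)))

    def excluded_boolean(self) -> np.ndarray:
        out = np.zeros(self.length, dtype=bool)
        for lo, hi in self.excluded:
            out[lo:hi] = True
        return out

    def analyzable_boolean(self) -> np.ndarray:
        return ~self.excluded_boolean()

    @property
    def n_excluded(self) -> int:
        return sum(hi - lo for lo, hi in self.excluded)

    def union(self, other: "SampleMask") -> "SampleMask":
        if self.length != other.length:
            raise ValueError("mask length mismatch")
        return SampleMask(self.length, self.excluded + other.excluded)


def sliding_detrend(signal: np.ndarray, sampling_rate_hz: float,
                    window_s: float = 3.0) -> np.ndarray:
    """Subtract the local linear trend seen by a centered sliding window.

    Implemented as an order-1 Savitzky-Golay smooth (equivalent to a centered
    moving average in the interior, with exact linear extrapolation at the
    edges), so constants and ramps vanish while oscillations faster than the
    window pass essentially unchanged.  Disjoint-window linear fits would
    instead distort in-band oscillations by tens of percent at the window
    seams, which is why a centered window is used.
    """
    x = np.asarray(signal, dtype=np.float64)
    win = int(round(window_s * sampling_rate_hz))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    if win > x.size:
        raise ValueError("detrend window longer than the signal")
    if win % 2 == 0:
        win += 1                      # savgol needs an odd window
        win = min(win, x.size if x.size % 2 else x.size - 1)
    trend = sps.savgol_filter(x, window_length=win, polyorder=1,
                              mode="interp")
    return x - trend


def high_amplitude_mask(detrended: np.ndarray, sampling_rate_hz: float,
                        threshold_uv: float = 900.0,
                        window_s: float = 3.0) -> SampleMask:
    """Exclude whole detrend-windows containing any sample with |x| > threshold.

    The inequality is strict: a sample at exactly the threshold survives.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    x = np.asarray(detrended, dtype=np.float64)
    win = int(round(window_s * sampling_rate_hz))
    bad = np.abs(x) > threshold_uv
    ranges = []
    for start in range(0, x.size, win):
        stop = min(start + win, x.size)
        if bad[start:stop].any():
            ranges.append((start, stop))
    return SampleMask(length=x.size, excluded=ranges)


def combine_masks(artifact: SampleMask, hypnogram: Hypnogram,
                  sampling_rate_hz: float,
                  keep_stages: Iterable[str] = ("N2", "N3")) -> SampleMask:
    """Analyzable = outside artifact ranges AND inside a kept-stage epoch."""
    n = artifact.length
    in_stage = hypnogram.sample_stage_mask(sampling_rate_hz, n, keep_stages)
    excluded = artifact.excluded_boolean() | ~in_stage
    return SampleMask.from_boolean(excluded)


@lru_cache(maxsize=32)
def _sos(order: int, lo: float, hi: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({nyq} Hz)")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _filtfilt(sos: np.ndarray, x: np.ndarray, fs: float,
              low_edge_hz: float) -> np.ndarray:
    # Reflective padding long enough for the slowest pole to settle; the
    # scipy default (a few filter lengths) is far too short for a 0.16 Hz
    # band edge and leaves a slow drift across the output.
    padlen = min(x.size - 1, int(round(3.0 * fs / low_edge_hz)))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def bandpass_slow(signal: np.ndarray, sampling_rate_hz: float) -> np.ndarray:
    """Zero-phase 6th-order Butterworth, 0.16–4 Hz."""
    if sampling_rate_hz <= 2 * SLOW_BAND[1]:
        raise ValueError("sampling rate too low for the slow-wave band")
    sos = _sos(SLOW_ORDER, *SLOW_BAND, sampling_rate_hz)
    return _filtfilt(sos, np.asarray(signal, dtype=np.float64),
                     sampling_rate_hz, SLOW_BAND[0])


def bandpass_spindle(signal: np.ndarray, sampling_rate_hz: float,
                     band: str) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth in one of the two spindle bands."""
    if band not in SPINDLE_BANDS:
        raise ValueError(f"band must be one of {sorted(SPINDLE_BANDS)}")
    lo, hi = SPINDLE_BANDS[band]
    sos = _sos(SPINDLE_ORDER, lo, hi, sampling_rate_hz)
    return _filtfilt(sos, np.asarray(signal, dtype=np.float64),
                     sampling_rate_hz, lo)


def butterworth_gain(order: int, lo: float, hi: float, fs: float,
                     freq_hz: float) -> float:
    """Magnitude response of the forward-backward filter at one frequency."""
    sos = _sos(order, lo, hi, fs)
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)  # applied twice: |H|^2
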