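"""Spindle detection by envelope thresholding in the two fast-spindle bands.

Events are contiguous stretches where the upper envelope of the band-passed
signal exceeds the 75th percentile of its moving-RMS trace over analyzable
N2+N3 samples, lasting 0.5–3.0 s.  Segments whose band-passed peak-to-trough
range exceeds 40 µV are treated as artifacts, and events whose peak envelope
deviates more than 8 SD from the event-population mean are rejected.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import hilbert

from .io_edf import EegRecording, Hypnogram
from .preprocess import (SPINDLE_BANDS, SampleMask, bandpass_spindle,
                         combine_masks, high_amplitude_mask, sliding_detrend)

log = logging.getLogger(__name__)

MIN_DUR_S = 0.5
MAX_DUR_S = 3.0
MAX_RANGE_UV = 40.0
OUTLIER_SD = 8.0
RMS_WINDOW_S = 0.5      # minimum event length; window of the moving RMS
MERGE_GAP_S = 0.1       # sub-threshold gaps shorter than this are bridged
THRESHOLD_PERCENTILE = 75.0


@dataclass
class SpindleEvent:
    """One detected spindle burst in a single band."""

    band: str
    t_onset_s: float
    t_offset_s: float
    duration_s: float
    peak_envelope_uv: float
    range_uv: float
    t_peak_env_s: float = 0.0
    stage: str = "N2"

    def validate(self) -> None:
        assert self.band in SPINDLE_BANDS
        assert MIN_DUR_S - 1e-9 <= self.duration_s <= MAX_DUR_S + 1e-9
        assert self.range_uv <= MAX_RANGE_UV + 1e-9
        assert self.t_offset_s > self.t_onset_s
        assert self.peak_envelope_uv > 0


def upper_envelope(bandpassed: np.ndarray,
                   sampling_rate_hz: float | None = None) -> np.ndarray:
    """Instantaneous amplitude of a band-limited signal (analytic magnitude)."""
    x = np.asarray(bandpassed, dtype=np.float64)
    # Pad to the next fast FFT length: hilbert() is a full-length FFT.
    from scipy.fft import next_fast_len
    n = x.size
    nfft = next_fast_len(n)
    env = np.abs(hilbert(x, N=nfft)[:n])
    return env


def moving_rms(x: np.ndarray, sampling_rate_hz: float,
               window_s: float = RMS_WINDOW_S) -> np.ndarray:
    win = max(1, int(round(window_s * sampling_rate_hz)))
    sq = np.asarray(x, dtype=np.float64) ** 2
    return np.sqrt(ndimage.uniform_filter1d(sq, size=win, mode="nearest"))


def spindle_threshold(envelope: np.ndarray, analyzable: SampleMask,
                      sampling_rate_hz: float,
                      rms_window_s: float = RMS_WINDOW_S,
                      percentile: float = THRESHOLD_PERCENTILE) -> float:
    """75th percentile (linear interpolation) of the envelope's moving RMS.

    Only analyzable samples enter the percentile; masked samples never
    contribute to the threshold estimate.
    """
    ok = analyzable.analyzable_boolean()
    if not ok.any():
        raise ValueError("no analyzable samples for threshold estimation")
    rms = moving_rms(envelope, sampling_rate_hz, rms_window_s)
    return float(np.percentile(rms[ok], percentile, method="linear"))


def _supra_segments(above: np.ndarray, fs: float,
                    merge_gap_s: float) -> list[tuple[int, int]]:
    """Contiguous True runs, after bridging sub-threshold gaps < merge_gap_s."""
    if not above.any():
        return []
    gap = int(round(merge_gap_s * fs))
    padded = np.concatenate([[False], above, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    merged: list[tuple[int, int]] = []
    for lo, hi in zip(starts, stops):
        if merged and lo - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    return merged


def detect_spindles(recording: EegRecording, hypnogram: Hypnogram, band: str,
                    keep_stages: Sequence[str] = ("N2", "N3"),
                    artifact_threshold_uv: float = 900.0,
                    detrend_window_s: float = 3.0,
                    rms_window_s: float = RMS_WINDOW_S,
                    merge_gap_s: float = MERGE_GAP_S,
                    max_range_uv: float = MAX_RANGE_UV,
                    outlier_sd: float = OUTLIER_SD) -> list[SpindleEvent]:
    """Full spindle pipeline for one band; events stage-stamped by onset epoch."""
    if band not in SPINDLE_BANDS:
        raise ValueError(f"band must be one of {sorted(SPINDLE_BANDS)}")
    hypnogram.check_paired(recording)
    fs = recording.sampling_rate_hz
    detrended = sliding_detrend(recording.samples, fs, detrend_window_s)
    artifact = high_amplitude_mask(detrended, fs, artifact_threshold_uv,
                                   detrend_window_s)
    mask = combine_masks(artifact, hypnogram, fs, keep_stages)
    bp = bandpass_spindle(detrended, fs, band)
    env = upper_envelope(bp)
    thr = spindle_threshold(env, mask, fs, rms_window_s)

    ok = mask.analyzable_boolean()
    above = (env > thr) & ok
    events: list[SpindleEvent] = []
    for lo, hi in _supra_segments(above, fs, merge_gap_s):
        dur = (hi - lo) / fs
        if not (MIN_DUR_S <= dur <= MAX_DUR_S):
            continue
        seg_bp = bp[lo:hi]
        rng = float(seg_bp.max() - seg_bp.min())
        if rng > max_range_uv:
            continue
        seg_env = env[lo:hi]
        pk = int(np.argmax(seg_env))
        events.append(SpindleEvent(
            band=band, t_onset_s=lo / fs, t_offset_s=hi / fs, duration_s=dur,
            peak_envelope_uv=float(seg_env[pk]), range_uv=rng,
            t_peak_env_s=(lo + pk) / fs,
            stage=hypnogram.stage_at(lo / fs)))
    events = reject_envelope_outliers(events, outlier_sd)
    return [e for e in events if e.stage in keep_stages]


def reject_envelope_outliers(events: Sequence[SpindleEvent],
                             outlier_sd: float = OUTLIER_SD,
                             ) -> list[SpindleEvent]:
    """Drop events whose peak envelope deviates > ``outlier_sd`` SD from the
    event-population mean (single pass, no re-iteration)."""
    if len(events) < 2:
        return list(events)
    peaks = np.array([e.peak_envelope_uv for e in events])
    m, s = peaks.mean(), peaks.std()
    return [e for e, p in zip(events, peaks)
            if abs(p - m) <= outlier_sd * s + 1e-12]
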