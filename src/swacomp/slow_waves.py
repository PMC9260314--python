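"""Slow-wave detection by zero-crossing half-wave pairing.

A candidate slow wave is a negative half-wave followed immediately by a
positive half-wave, delimited by three consecutive zero crossings of the
0.16–4 Hz filtered signal, with a full-wave duration of 0.25–2.5 s
(full-wave frequency 0.4–4 Hz).  Selection then removes candidates whose
extremes exceed ±200 µV, rejects 4-SD amplitude outliers, and keeps only
waves whose trough depth and peak height are both in the top 50 % of the
night's candidate population (the median boundary is inclusive, so ties
survive).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_edf import EegRecording, Hypnogram
from .preprocess import (SampleMask, bandpass_slow, combine_masks,
                         high_amplitude_mask, sliding_detrend)

log = logging.getLogger(__name__)

MIN_DUR_S = 0.25   # full-wave duration bounds: 0.4–4 Hz
MAX_DUR_S = 2.5
AMP_CEILING_UV = 200.0
OUTLIER_SD = 4.0


@dataclass
class SlowWaveEvent:
    """One trough-then-peak slow wave delimited by three zero crossings."""

    t_down_zc_s: float
    t_trough_s: float
    trough_uv: float
    t_up_zc_s: float
    t_peak_s: float
    peak_uv: float
    t_end_zc_s: float
    duration_s: float
    stage: str = "N2"

    def validate(self) -> None:
        assert self.trough_uv < 0 < self.peak_uv
        assert (self.t_down_zc_s < self.t_trough_s < self.t_up_zc_s
                < self.t_peak_s < self.t_end_zc_s)
        assert MIN_DUR_S - 1e-9 <= self.duration_s <= MAX_DUR_S + 1e-9
        assert abs(self.trough_uv) <= AMP_CEILING_UV
        assert abs(self.peak_uv) <= AMP_CEILING_UV


def find_half_wave_pairs(filtered: np.ndarray, sampling_rate_hz: float,
                         mask: Optional[SampleMask] = None,
                         min_dur_s: float = MIN_DUR_S,
                         max_dur_s: float = MAX_DUR_S) -> list[SlowWaveEvent]:
    """Enumerate trough-first half-wave pairs within the duration band.

    Candidates overlapping any excluded mask range are dropped; an incomplete
    trailing half-wave (no closing zero crossing) never forms a candidate.
    """
    x = np.asarray(filtered, dtype=np.float64)
    fs = sampling_rate_hz
    neg = x < 0
    down = np.flatnonzero(~neg[:-1] & neg[1:]) + 1   # first sample below zero
    up = np.flatnonzero(neg[:-1] & ~neg[1:]) + 1     # first sample back at/above

    if mask is not None:
        excluded = mask.excluded_boolean()
        bad_cum = np.concatenate([[0], np.cumsum(excluded)])
    else:
        bad_cum = None

    events: list[SlowWaveEvent] = []
    for i in range(down.size - 1):
        z0, z2 = down[i], down[i + 1]
        dur = (z2 - z0) / fs
        if not (min_dur_s <= dur <= max_dur_s):
            continue
        j = np.searchsorted(up, z0)
        if j >= up.size or up[j] >= z2:
            continue
        z1 = up[j]
        if bad_cum is not None and bad_cum[z2] - bad_cum[z0] > 0:
            continue
        trough_i = z0 + int(np.argmin(x[z0:z1]))
        peak_i = z1 + int(np.argmax(x[z1:z2]))
        trough, peak = float(x[trough_i]), float(x[peak_i])
        if not (trough < 0 < peak):
            continue
        events.append(SlowWaveEvent(
            t_down_zc_s=z0 / fs, t_trough_s=trough_i / fs, trough_uv=trough,
            t_up_zc_s=z1 / fs, t_peak_s=peak_i / fs, peak_uv=peak,
            t_end_zc_s=z2 / fs, duration_s=dur))
    return events


def amplitude_select(candidates: Sequence[SlowWaveEvent],
                     ceiling_uv: float = AMP_CEILING_UV,
                     outlier_sd: float = OUTLIER_SD) -> list[SlowWaveEvent]:
    """Amplitude ceiling, 4-SD outlier rejection, then joint top-50 % rule.

    Step 1 removes candidates with |trough| or |peak| above the ±200 µV
    ceiling.  Step 2 removes candidates whose trough or peak deviates more
    than ``outlier_sd`` standard deviations from the respective population
    mean (computed once, no iteration).  Step 3 keeps candidates whose
    |trough| and peak are both at or above the population medians.
    """
    if len(candidates) == 0:
        raise ValueError("amplitude_select needs at least one candidate")
    evs = [e for e in candidates
           if abs(e.trough_uv) <= ceiling_uv and abs(e.peak_uv) <= ceiling_uv]
    if not evs:
        return []
    troughs = np.array([e.trough_uv for e in evs])
    peaks = np.array([e.peak_uv for e in evs])
    mt, st = troughs.mean(), troughs.std()
    mp, sp = peaks.mean(), peaks.std()
    keep = ((np.abs(troughs - mt) <= outlier_sd * st + 1e-12)
            & (np.abs(peaks - mp) <= outlier_sd * sp + 1e-12))
    evs = [e for e, k in zip(evs, keep) if k]
    if not evs:
        return []
    abs_troughs = np.array([abs(e.trough_uv) for e in evs])
    peaks = np.array([e.peak_uv for e in evs])
    med_t = np.median(abs_troughs)
    med_p = np.median(peaks)
    return [e for e in evs
            if abs(e.trough_uv) >= med_t and e.peak_uv >= med_p]


def detect_slow_waves(recording: EegRecording, hypnogram: Hypnogram,
                      keep_stages: Sequence[str] = ("N2", "N3"),
                      artifact_threshold_uv: float = 900.0,
                      detrend_window_s: float = 3.0,
                      min_dur_s: float = MIN_DUR_S,
                      max_dur_s: float = MAX_DUR_S) -> list[SlowWaveEvent]:
    """Full slow-wave pipeline: detrend, mask, filter, pair, select, stamp."""
    hypnogram.check_paired(recording)
    fs = recording.sampling_rate_hz
    detrended = sliding_detrend(recording.samples, fs, detrend_window_s)
    artifact = high_amplitude_mask(detrended, fs, artifact_threshold_uv,
                                   detrend_window_s)
    mask = combine_masks(artifact, hypnogram, fs, keep_stages)
    filtered = bandpass_slow(detrended, fs)
    candidates = find_half_wave_pairs(filtered, fs, mask,
                                      min_dur_s=min_dur_s, max_dur_s=max_dur_s)
    if not candidates:
        return []
    selected = amplitude_select(candidates)
    selected.sort(key=lambda e: e.t_trough_s)
    out = []
    for ev in selected:
        stage = hypnogram.stage_at(ev.t_trough_s)
        if stage not in keep_stages:
            # trough in an analyzable window whose epoch is not kept
            # (boundary rounding); drop rather than mislabel
            continue
        ev.stage = stage
        out.append(ev)
    return out
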