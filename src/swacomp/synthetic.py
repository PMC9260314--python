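"""Synthetic overnight polysomnography with known ground truth.

The generator emulates the statistical structure the detection pipeline is
built for: a staged night with multiple NREM cycles, 1/f^β background EEG,
biphasic slow oscillations placed at stage-dependent densities, and
Gaussian-windowed spindle bursts in the late-fast (12 Hz) and early-fast
(16 Hz) bands attached to a stage- and subtype-dependent fraction of
slow-wave troughs at lags drawn strictly inside the detector's 0.2–1.5 s
coupling window.  An ``lf_shift`` knob raises the late-fast coupling
probability, mimicking the shift in SWA composition reported in aging
adults.

Slow-band NREM EEG is close to a continuous oscillation, so default
slow-wave densities are high (tens of waves per minute in N3) — consistent
with zero-crossing detectors counting several thousand selected waves per
night.  Everything injected is recorded as ground truth, and generation is
deterministic under the config seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_edf import EegRecording, Hypnogram, write_hypnogram, write_recording
from .preprocess import SPINDLE_BANDS

EXCLUDED_SPINDLE_BAND = (13.5, 14.5)


@dataclass
class SimulationConfig:
    duration_h: float = 8.0
    sampling_rate_hz: float = 200.0
    n_nrem_cycles: int = 4
    stage_epoch_s: float = 30.0
    #: slow waves per minute per stage; N3 slow-band activity is near-continuous
    sw_rate_per_min: dict = field(default_factory=lambda: {"N3": 33.0, "N2": 22.0})
    sw_amp_uv: tuple[float, float] = (80.0, 10.0)        # trough depth mean/SD
    spindle_coupling_prob: dict = field(default_factory=lambda: {
        ("N3", "late_fast"): 0.45, ("N3", "early_fast"): 0.20,
        ("N2", "late_fast"): 0.25, ("N2", "early_fast"): 0.35})
    lag_dist: tuple[float, float] = (0.25, 1.4)          # uniform support, s
    spindle_freq_hz: dict = field(default_factory=lambda: {
        "late_fast": 12.0, "early_fast": 16.0})
    #: envelope peak mean/SD; clipped to 9-16 µV so peak-to-peak range stays
    #: safely below the 40 µV artifact ceiling even with noise on top
    spindle_amp_uv: tuple[float, float] = (13.0, 2.5)
    spindle_dur_s: tuple[float, float] = (1.2, 0.25)     # clipped to 0.8-2.0 s
    uncoupled_spindle_rate_per_min: float = 3.0          # per band, N2+N3
    noise_exponent: float = 1.0                          # 1/f^beta
    noise_scale_uv: float = 15.0                         # broadband RMS
    lf_shift: float = 0.0                                # aging knob
    seed: int = 0

    def validate(self) -> None:
        for p in self.spindle_coupling_prob.values():
            if not 0 <= p <= 1:
                raise ValueError("coupling probabilities must be in [0, 1]")
        if not 0 <= self.lf_shift <= 1:
            raise ValueError("lf_shift must be in [0, 1]")
        for r in self.sw_rate_per_min.values():
            if r < 0:
                raise ValueError("slow-wave rates must be non-negative")
        lo, hi = EXCLUDED_SPINDLE_BAND
        for band, f in self.spindle_freq_hz.items():
            if lo <= f <= hi:
                raise ValueError(f"{band} carrier {f} Hz lies in the excluded "
                                 f"{lo}-{hi} Hz band")
            blo, bhi = SPINDLE_BANDS[band]
            if not blo <= f <= bhi:
                raise ValueError(f"{band} carrier {f} Hz outside its band")


@dataclass
class GroundTruth:
    slow_waves: list          # (t_trough_s, trough_uv, stage)
    spindles: list            # (t_onset_s, duration_s, band, amp_uv)
    couples: list             # (sw_index, spindle_index, subtype, lag_s)

    def sw_times(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.slow_waves])

    def spindle_times(self, band: Optional[str] = None) -> np.ndarray:
        return np.array([t for t, _, b, _ in self.spindles
                         if band is None or b == band])


def simulate_hypnogram(config: SimulationConfig) -> Hypnogram:
    """Staged night: wake onset, then N1→N2→N3→N2→REM cycles, trailing wake."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_epochs = int(round(config.duration_h * 3600 / config.stage_epoch_s))
    if config.n_nrem_cycles == 0:
        return Hypnogram(config.stage_epoch_s, ("W",) * max(n_epochs, 1))
    onset = max(1, int(round(0.05 * n_epochs)))
    sleep_epochs = n_epochs - onset
    cyc_len = sleep_epochs // config.n_nrem_cycles
    if cyc_len < 5:
        raise ValueError("duration too short for the requested NREM cycles")
    stages: list[str] = ["W"] * onset
    # within-cycle fractions; mild seeded jitter keeps nights distinct
    base = [("N1", 0.05), ("N2", 0.35), ("N3", 0.25), ("N2", 0.20), ("REM", 0.15)]
    for _ in range(config.n_nrem_cycles):
        fr = np.array([f for _, f in base])
        fr = fr * rng.uniform(0.85, 1.15, size=fr.size)
        fr = fr / fr.sum()
        counts = np.maximum(1, np.round(fr * cyc_len).astype(int))
        while counts.sum() > cyc_len:
            counts[np.argmax(counts)] -= 1
        for (st, _), c in zip(base, counts):
            stages.extend([st] * int(c))
    stages.extend(["W"] * (n_epochs - len(stages)))
    return Hypnogram(config.stage_epoch_s, tuple(stages[:n_epochs]))


def _pink_noise(n: int, beta: float, rms: float, rng: np.random.Generator,
                fs: float) -> np.ndarray:
    """1/f^beta Gaussian noise by FFT spectral shaping, scaled to target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-beta / 2)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    x *= rms / max(x.std(), 1e-12)
    return x


def _sw_waveform(dur_neg: float, dur_pos: float, trough_uv: float,
                 peak_uv: float, fs: float) -> np.ndarray:
    n_neg = max(2, int(round(dur_neg * fs)))
    n_pos = max(2, int(round(dur_pos * fs)))
    t_neg = np.arange(n_neg) / n_neg
    t_pos = np.arange(n_pos) / n_pos
    return np.concatenate([trough_uv * np.sin(np.pi * t_neg),
                           peak_uv * np.sin(np.pi * t_pos)])


def simulate_recording(config: SimulationConfig, hypnogram: Hypnogram,
                       subject_id: str = "synthetic",
                       channel_label: str = "C3",
                       ) -> tuple[EegRecording, GroundTruth]:
    """Render the night: pink noise + slow oscillations + coupled spindles."""
    config.validate()
    fs = config.sampling_rate_hz
    epoch_s = hypnogram.epoch_seconds
    n = int(round(hypnogram.duration_s * fs))
    ss = np.random.SeedSequence([config.seed, 29])
    rng_noise, rng_sw, rng_sp = [np.random.default_rng(s) for s in ss.spawn(3)]

    signal = _pink_noise(n, config.noise_exponent, config.noise_scale_uv,
                         rng_noise, fs)

    # --- slow oscillations: sequential placement within same-stage runs ----
    sw_list: list[tuple[float, float, str]] = []
    sw_shapes: list[tuple[int, np.ndarray, float]] = []   # (start idx, wf, t_trough)
    stages = hypnogram.stages
    i = 0
    while i < len(stages):
        j = i
        while j < len(stages) and stages[j] == stages[i]:
            j += 1
        stage = stages[i]
        rate = config.sw_rate_per_min.get(stage, 0.0)
        if rate > 0:
            t0, t1 = i * epoch_s, j * epoch_s
            mean_dur = 1.2
            gap_mean = max(60.0 / rate - mean_dur, 0.05)
            t = t0 + rng_sw.exponential(gap_mean)
            while True:
                dur = rng_sw.uniform(0.8, 1.6)
                if t + dur >= t1:
                    break
                dn = dur * rng_sw.uniform(0.45, 0.55)
                dp = dur - dn
                amp = float(np.clip(rng_sw.normal(*config.sw_amp_uv), 40, 190))
                peak = float(np.clip(amp * rng_sw.uniform(0.45, 0.6), 10, 190))
                wf = _sw_waveform(dn, dp, -amp, peak, fs)
                start = int(round(t * fs))
                t_trough = t + dn / 2
                sw_shapes.append((start, wf, t_trough))
                sw_list.append((t_trough, -amp, stage))
                t = t + dur + rng_sw.exponential(gap_mean)
        i = j

    for start, wf, _ in sw_shapes:
        stop = min(start + wf.size, n)
        signal[start:stop] += wf[:stop - start]

    # --- spindles: coupled to troughs, plus a small uncoupled rate ---------
    import bisect

    spindle_list: list[tuple[float, float, str, float]] = []
    couples: list[tuple[int, int, str, float]] = []
    placed: dict[str, list[tuple[float, float]]] = {"late_fast": [],
                                                    "early_fast": []}

    def _collides(onset: float, end: float, band: str) -> bool:
        iv = placed[band]
        i = bisect.bisect_left(iv, (onset, end))
        for k in (i - 1, i):
            if 0 <= k < len(iv):
                lo, hi = iv[k]
                if min(end, hi) - max(onset, lo) > -0.3:  # require 0.3 s gap
                    return True
        return False

    def _place_burst(onset: float, band: str) -> Optional[int]:
        dur = float(np.clip(rng_sp.normal(*config.spindle_dur_s), 0.8, 2.0))
        amp = float(np.clip(rng_sp.normal(*config.spindle_amp_uv), 9.0, 16.0))
        if onset + dur >= n / fs or _collides(onset, onset + dur, band):
            return None
        start = int(round(onset * fs))
        m = int(round(dur * fs))
        tt = np.arange(m) / fs
        carrier = np.sin(2 * np.pi * config.spindle_freq_hz[band] * tt
                         + rng_sp.uniform(0, 2 * np.pi))
        # tapered-cosine envelope: waxing/waning flanks, sustained core
        edge = dur / 4
        envelope = np.ones(m)
        ramp = tt < edge
        envelope[ramp] = np.sin(np.pi * tt[ramp] / (2 * edge)) ** 2
        ramp = tt > dur - edge
        envelope[ramp] = np.sin(np.pi * (dur - tt[ramp]) / (2 * edge)) ** 2
        signal[start:start + m] += amp * envelope * carrier
        spindle_list.append((onset, dur, band, amp))
        bisect.insort(placed[band], (onset, onset + dur))
        return len(spindle_list) - 1

    for sw_idx, (t_trough, _, stage) in enumerate(sw_list):
        p_lf = min(1.0, config.spindle_coupling_prob.get((stage, "late_fast"), 0)
                   + config.lf_shift)
        p_ef = config.spindle_coupling_prob.get((stage, "early_fast"), 0)
        p_tot = min(1.0, p_lf + p_ef)
        if rng_sp.uniform() >= p_tot or p_tot == 0:
            continue
        band = "late_fast" if rng_sp.uniform() < p_lf / (p_lf + p_ef) else "early_fast"
        lag = rng_sp.uniform(*config.lag_dist)
        sp_idx = _place_burst(t_trough + lag, band)
        if sp_idx is not None:
            couples.append((sw_idx, sp_idx,
                            "LF_SW" if band == "late_fast" else "EF_SW", lag))

    if config.uncoupled_spindle_rate_per_min > 0:
        for e, stage in enumerate(stages):
            if stage not in ("N2", "N3"):
                continue
            for band in ("late_fast", "early_fast"):
                k = rng_sp.poisson(config.uncoupled_spindle_rate_per_min
                                   * epoch_s / 60)
                for t in np.sort(rng_sp.uniform(e * epoch_s, (e + 1) * epoch_s,
                                                size=k)):
                    _place_burst(float(t), band)

    rec = EegRecording(subject_id=subject_id, channel_label=channel_label,
                       reference_label=None, sampling_rate_hz=fs,
                       samples=signal)
    truth = GroundTruth(slow_waves=sw_list, spindles=spindle_list,
                        couples=couples)
    return rec, truth


def score_detection(detected_times: Sequence[float],
                    truth_times: Sequence[float],
                    tolerance_s: float) -> tuple[float, float, list]:
    """Greedy one-to-one nearest-time matching within a tolerance.

    Returns (precision, recall, matched (detected_idx, truth_idx) pairs).
    Empty detections yield precision 1.0 by convention (flagged by n = 0).
    """
    if tolerance_s <= 0:
        raise ValueError("tolerance must be positive")
    det = np.asarray(detected_times, float)
    tru = np.asarray(truth_times, float)
    if det.size == 0:
        return 1.0, 0.0 if tru.size else 1.0, []
    if tru.size == 0:
        return 0.0, 1.0, []
    order_t = np.argsort(tru)
    tru_sorted = tru[order_t]
    pairs = []
    for di, t in enumerate(det):
        j = np.searchsorted(tru_sorted, t)
        for k in (j - 1, j):
            if 0 <= k < tru_sorted.size:
                dt = abs(tru_sorted[k] - t)
                if dt <= tolerance_s:
                    pairs.append((dt, di, int(order_t[k])))
    pairs.sort()
    used_d, used_t, matched = set(), set(), []
    for dt, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matched.append((di, ti))
    precision = len(matched) / det.size
    recall = len(matched) / tru.size
    return precision, recall, matched


def simulate_subject(config: SimulationConfig, out_dir: str | Path,
                     subject_id: str = "synthetic",
                     channel_label: str = "C3") -> dict[str, Path]:
    """Write a full synthetic subject (EDF + hypnogram + truth TSV) to disk."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hyp = simulate_hypnogram(config)
    rec, truth = simulate_recording(config, hyp, subject_id, channel_label)
    edf = write_recording(rec, out_dir / f"{subject_id}.edf")
    hypf = write_hypnogram(hyp, out_dir / f"{subject_id}.hyp")
    rows = [{"kind": "slow_wave", "t_s": t, "amp_uv": a, "label": st}
            for t, a, st in truth.slow_waves]
    rows += [{"kind": "spindle", "t_s": t, "amp_uv": a, "label": b,
              "duration_s": d} for t, d, b, a in truth.spindles]
    rows += [{"kind": "couple", "t_s": truth.slow_waves[si][0], "label": sub,
              "sw_index": si, "spindle_index": pi, "lag_s": lag}
             for si, pi, sub, lag in truth.couples]
    truth_path = out_dir / f"{subject_id}_truth.tsv"
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)
    return {"edf": edf, "hypnogram": hypf, "truth": truth_path}
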