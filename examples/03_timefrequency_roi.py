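"""Baseline-normalized peri-trough time-frequency power in spindle ROIs.

Each coupled slow-wave trough is centered in a 5-s window; an 8-cycle
Morlet transform (4-20 Hz, 0.25 Hz steps) of those windows is averaged and
divided per-frequency by the mean of matched preceding 5-s baselines.  ROI
power is the mean normalized amplitude over the spindle band crossed with
the post-trough coupling window; values above 1 mean spindle-band power is
elevated around troughs relative to baseline.
"""
from swacomp import (baseline_segments, classify_coupling, detect_slow_waves,
                     detect_spindles, normalize_and_average,
                     peri_event_segments, roi_power, sliding_detrend)
from swacomp.synthetic import (SimulationConfig, simulate_hypnogram,
                               simulate_recording)
from swacomp.timefreq import DEFAULT_ROIS, RoiSpec, morlet_tfr_batch

config = SimulationConfig(duration_h=1.0, sampling_rate_hz=128.0,
                          n_nrem_cycles=2, seed=5)
hypnogram = simulate_hypnogram(config)
recording, _ = simulate_recording(config, hypnogram)
fs = recording.sampling_rate_hz

slow_waves = detect_slow_waves(recording, hypnogram)
coupled, _ = classify_coupling(
    slow_waves,
    detect_spindles(recording, hypnogram, "late_fast"),
    detect_spindles(recording, hypnogram, "early_fast"))
signal = sliding_detrend(recording.samples, fs)

for band, subtype in (("late_fast", "LF_SW"), ("early_fast", "EF_SW")):
    events = [c.slow_wave for c in coupled if c.subtype == subtype]
    segments, kept, _ = peri_event_segments(signal, fs, events)
    baselines = baseline_segments(signal, fs, kept, slow_waves)
    normalized = normalize_and_average(morlet_tfr_batch(segments, fs),
                                       morlet_tfr_batch(baselines, fs))
    roi = RoiSpec(name=band, **DEFAULT_ROIS[band])
    power = roi_power(normalized, roi)
    print(f"{subtype}: {len(segments)} events, {len(baselines)} baselines, "
          f"ROI power {power:.2f}x baseline")
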