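"""Simulate a night of sleep EEG and detect slow waves and spindles.

Generates one hour of synthetic polysomnography (1/f background, staged
hypnogram, injected slow oscillations and spindle bursts with known ground
truth), runs both detectors, and scores them against the ground truth.
"""
from swacomp import detect_slow_waves, detect_spindles
from swacomp.synthetic import (SimulationConfig, score_detection,
                               simulate_hypnogram, simulate_recording)

config = SimulationConfig(duration_h=1.0, sampling_rate_hz=128.0,
                          n_nrem_cycles=2, seed=1)
hypnogram = simulate_hypnogram(config)
recording, truth = simulate_recording(config, hypnogram)
print(f"simulated {recording.duration_s / 60:.0f} min at "
      f"{recording.sampling_rate_hz:.0f} Hz; "
      f"{len(truth.slow_waves)} slow waves injected")

slow_waves = detect_slow_waves(recording, hypnogram)
precision, recall, _ = score_detection(
    [e.t_trough_s for e in slow_waves], truth.sw_times(), tolerance_s=0.25)
print(f"slow waves: {len(slow_waves)} detected, "
      f"precision {precision:.2f}, recall {recall:.2f}")
# precision = detected troughs matching an injected wave within 250 ms;
# recall = injected waves recovered by the detector

for band in ("late_fast", "early_fast"):
    spindles = detect_spindles(recording, hypnogram, band)
    det = [(e.t_onset_s + e.t_offset_s) / 2 for e in spindles]
    tru = [t + d / 2 for t, d, b, a in truth.spindles if b == band]
    p, r, _ = score_detection(det, tru, tolerance_s=0.5)
    print(f"{band:>10s} spindles: {len(spindles)} detected, "
          f"precision {p:.2f}, recall {r:.2f}")
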