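"""Couple slow waves to spindle subtypes and summarize SWA composition.

A slow wave whose trough is followed within 0.2-1.5 s by a late-fast
(10-13.5 Hz) spindle is an LF-SW event; by an early-fast (14.5-18 Hz)
spindle, an EF-SW event.  The percentage of LF-SW events per stage and per
normalized-NREM time bin is the composition of slow-wave activity.
"""
from swacomp import (classify_coupling, detect_slow_waves, detect_spindles,
                     high_lf_bin_count, normalized_nrem_bins,
                     stage_percentages)
from swacomp.synthetic import (SimulationConfig, simulate_hypnogram,
                               simulate_recording)

config = SimulationConfig(duration_h=1.0, sampling_rate_hz=128.0,
                          n_nrem_cycles=2, seed=3)
hypnogram = simulate_hypnogram(config)
recording, truth = simulate_recording(config, hypnogram)

slow_waves = detect_slow_waves(recording, hypnogram)
late_fast = detect_spindles(recording, hypnogram, "late_fast")
early_fast = detect_spindles(recording, hypnogram, "early_fast")
coupled, unclassified = classify_coupling(slow_waves, late_fast, early_fast)
n_lf = sum(1 for c in coupled if c.subtype == "LF_SW")
print(f"{len(slow_waves)} slow waves -> {n_lf} LF-SW, "
      f"{len(coupled) - n_lf} EF-SW, {len(unclassified)} unclassified")
# the three counts always partition the slow-wave total

composition = stage_percentages(coupled, hypnogram)
for stage in ("N3", "N2"):
    c = composition[stage]
    print(f"stage {stage}: {c.n_lf} LF vs {c.n_ef} EF "
          f"-> {c.pct_lf:.1f}% late-fast")
# deeper N3 sleep carries a higher late-fast share than N2, so the
# composition of SWA rises and falls with depth of sleep across the night

bins = normalized_nrem_bins(coupled, hypnogram, n_bins=100)
n_high = high_lf_bin_count(bins, threshold_pct=80.0)
print(f"{n_high} of 100 normalized-NREM bins are >= 80% late-fast")
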