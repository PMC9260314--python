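"""Shared fixtures: synthetic nights reused across detection-level tests.

Test nights are deliberately short (30–60 min, 128 Hz) so the whole suite
runs in minutes; the generator's amplitude/noise/coupling defaults are the
package defaults.
"""
import numpy as np
import pytest
from hypothesis import settings

from swacomp.synthetic import (SimulationConfig, simulate_hypnogram,
                               simulate_recording)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_probe_recording(freq, dur_s=1.0, amp=12.0, total_s=240.0, seed=0,
                         onset_s=100.0, fs=128.0):
    """Low pink noise + background spindle bursts in both bands + one probe.

    The background population (12 bursts/min alternating 12 and 16 Hz,
    placed away from the probe window) puts the envelope threshold in its
    operating regime; the probe burst at ``onset_s`` carries the frequency
    under test.
    """
    from swacomp.io_edf import EegRecording, Hypnogram

    rng = np.random.default_rng(seed)
    n = int(total_s * fs)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    x = np.fft.irfft(spec * np.where(f > 0, np.maximum(f, 0.1) ** -0.5, 0), n)
    x *= 5.0 / x.std()

    def _burst(t0, f0, a, d):
        m = int(d * fs)
        tt = np.arange(m) / fs
        x[int(t0 * fs):int(t0 * fs) + m] += (
            a * np.sin(np.pi * tt / d) * np.sin(2 * np.pi * f0 * tt))

    k = 0
    t0 = 3.0
    while t0 < total_s - 3.0:
        if abs(t0 - onset_s) > 6.0:          # keep the probe window clean
            _burst(t0, 12.0 if k % 2 == 0 else 16.0, 14.0, 1.3)
            k += 1
        t0 += 2.0                            # ~15 bursts/min per band
    _burst(onset_s, freq, amp, dur_s)
    rec = EegRecording("probe", "C3", None, fs, x)
    hyp = Hypnogram(30, ("N2",) * int(total_s / 30))
    return rec, hyp


@pytest.fixture(scope="session")
def short_night():
    """30-min single-cycle night with ground truth (seed 3)."""
    cfg = SimulationConfig(duration_h=0.5, sampling_rate_hz=128.0,
                           n_nrem_cycles=1, seed=3)
    hyp = simulate_hypnogram(cfg)
    rec, truth = simulate_recording(cfg, hyp)
    return cfg, hyp, rec, truth


@pytest.fixture(scope="session")
def one_hour_night():
    """60-min two-cycle night with ground truth (seed 1)."""
    cfg = SimulationConfig(duration_h=1.0, sampling_rate_hz=128.0,
                           n_nrem_cycles=2, seed=1)
    hyp = simulate_hypnogram(cfg)
    rec, truth = simulate_recording(cfg, hyp)
    return cfg, hyp, rec, truth


@pytest.fixture(scope="session")
def detected_night(one_hour_night):
    """Full detection output (slow waves, both spindle bands, coupling)."""
    from swacomp.coupling import classify_coupling
    from swacomp.slow_waves import detect_slow_waves
    from swacomp.spindles import detect_spindles

    cfg, hyp, rec, truth = one_hour_night
    sw = detect_slow_waves(rec, hyp)
    lf = detect_spindles(rec, hyp, "late_fast")
    ef = detect_spindles(rec, hyp, "early_fast")
    coupled, unclassified = classify_coupling(sw, lf, ef)
    return dict(cfg=cfg, hyp=hyp, rec=rec, truth=truth, sw=sw, lf=lf, ef=ef,
                coupled=coupled, unclassified=unclassified)
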