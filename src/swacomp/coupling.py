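"""Trough-locked pairing of slow waves with spindle subtypes.

A spindle whose reference time (onset by default) falls 0.2–1.5 s after a
slow-wave trough marks that wave as a coupled event: late-fast spindle →
LF-SW, early-fast spindle → EF-SW.  The 0.2 s buffer after the trough
excludes slow-spindle activity that shares frequency content with late-fast
spindles and precedes the trough.  Slow waves matched by both bands at once
are left unclassified (never double-counted), each spindle is claimed by at
most one slow wave (earliest trough wins), and waves with no qualifying
spindle stay unclassified — so LF + EF + unclassified always partitions the
slow-wave count.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .slow_waves import SlowWaveEvent
from .spindles import SpindleEvent

COUPLING_WINDOW_S = (0.2, 1.5)
SUBTYPE_OF_BAND = {"late_fast": "LF_SW", "early_fast": "EF_SW"}


@dataclass
class CoupledEvent:
    """A slow wave paired with one spindle subtype; the unit of SWA composition."""

    slow_wave: SlowWaveEvent
    spindle: SpindleEvent
    subtype: str            # LF_SW or EF_SW
    lag_s: float            # spindle reference time - slow-wave trough time
    sw_channel: str = ""
    spindle_channel: str = ""

    def validate(self) -> None:
        assert COUPLING_WINDOW_S[0] - 1e-9 <= self.lag_s <= COUPLING_WINDOW_S[1] + 1e-9
        assert self.subtype == SUBTYPE_OF_BAND[self.spindle.band]


def _reference_time(sp: SpindleEvent, reference: str) -> float:
    if reference == "onset":
        return sp.t_onset_s
    if reference == "peak":
        return sp.t_peak_env_s
    raise ValueError("reference must be 'onset' or 'peak'")


def classify_coupling(slow_waves: Sequence[SlowWaveEvent],
                      late_fast: Sequence[SpindleEvent],
                      early_fast: Sequence[SpindleEvent],
                      window_s: tuple[float, float] = COUPLING_WINDOW_S,
                      reference: str = "onset",
                      sw_channel: str = "", spindle_channel: str = "",
                      ) -> tuple[list[CoupledEvent], list[SlowWaveEvent]]:
    """Greedy trough-ordered coupling; returns (coupled, unclassified)."""
    for name, evs, key in (("slow_waves", slow_waves, lambda e: e.t_trough_s),
                           ("late_fast", late_fast, lambda e: e.t_onset_s),
                           ("early_fast", early_fast, lambda e: e.t_onset_s)):
        times = [key(e) for e in evs]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"{name} events must be time-sorted")

    lo, hi = window_s
    pools = {"late_fast": [[_reference_time(s, reference), s, False]
                           for s in late_fast],
             "early_fast": [[_reference_time(s, reference), s, False]
                            for s in early_fast]}
    coupled: list[CoupledEvent] = []
    unclassified: list[SlowWaveEvent] = []
    for sw in slow_waves:
        t0, t1 = sw.t_trough_s + lo, sw.t_trough_s + hi
        hits = {}
        for band, pool in pools.items():
            cand = [item for item in pool
                    if not item[2] and t0 <= item[0] <= t1]
            if cand:
                hits[band] = min(cand, key=lambda item: item[0])
        if len(hits) != 1:
            unclassified.append(sw)     # no match, or ambiguous (both bands)
            continue
        band, item = next(iter(hits.items()))
        item[2] = True                  # spindle claimed
        coupled.append(CoupledEvent(
            slow_wave=sw, spindle=item[1], subtype=SUBTYPE_OF_BAND[band],
            lag_s=item[0] - sw.t_trough_s,
            sw_channel=sw_channel, spindle_channel=spindle_channel))
    return coupled, unclassified
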