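"""EDF and hypnogram I/O and the core recording data model.

All amplitudes inside the package are microvolts (µV); the conversion from
EDF physical units happens exactly once, here, at read time.
"""
from __future__ import annotations

import dataclasses
import io
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

STAGES = ("W", "N1", "N2", "N3", "REM", "UNSCORABLE")

#: Stage-token maps per hypnogram dialect.  DREAMS files score one line per
#: (typically 5-s) epoch with numeric codes (S3/S4 both map onto AASM N3);
#: NSRR/Profusion XML uses 0–5 integer stage codes.  Unknown tokens always
#: map to UNSCORABLE.
STAGE_TOKEN_MAPS: dict[str, dict[str, str]] = {
    "plain_text": {
        "W": "W", "WAKE": "W", "N1": "N1", "N2": "N2", "N3": "N3",
        "REM": "REM", "R": "REM", "UNSCORABLE": "UNSCORABLE",
    },
    "dreams": {
        "5": "W", "4": "REM", "3": "N1", "2": "N2", "1": "N3", "0": "N3",
        "-1": "UNSCORABLE", "-2": "UNSCORABLE", "-3": "UNSCORABLE",
    },
    "nsrr_xml": {
        "0": "W", "1": "N1", "2": "N2", "3": "N3", "4": "N3", "5": "REM",
    },
}


@dataclass
class EegRecording:
    """One referenced EEG channel: samples in µV at a uniform rate."""

    subject_id: str
    channel_label: str
    reference_label: Optional[str]
    sampling_rate_hz: float
    samples: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class Hypnogram:
    """Fixed-length-epoch AASM stage labels."""

    epoch_seconds: float
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        self.stages = tuple(self.stages)
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_seconds

    def stage_at(self, t_s: float) -> str:
        """Stage of the epoch containing time ``t_s`` (UNSCORABLE off the end)."""
        idx = int(t_s // self.epoch_seconds)
        if t_s < 0 or idx >= self.n_epochs:
            return "UNSCORABLE"
        return self.stages[idx]

    def check_paired(self, recording: EegRecording) -> None:
        """Enforce the pairing contract: durations within one epoch."""
        if abs(self.duration_s - recording.duration_s) > self.epoch_seconds:
            raise ValueError(
                f"hypnogram covers {self.duration_s:.0f} s but recording lasts "
                f"{recording.duration_s:.0f} s (> one epoch apart)"
            )

    def sample_stage_mask(self, sampling_rate_hz: float, n_samples: int,
                          keep_stages: Iterable[str]) -> np.ndarray:
        """Boolean array, True where the sample lies in a kept-stage epoch."""
        keep = set(keep_stages)
        out = np.zeros(n_samples, dtype=bool)
        spe = self.epoch_seconds * sampling_rate_hz
        for i, st in enumerate(self.stages):
            if st in keep:
                lo = int(round(i * spe))
                hi = min(int(round((i + 1) * spe)), n_samples)
                out[lo:hi] = True
        return out


# ---------------------------------------------------------------------------
# EDF reading (via MNE) and a minimal 16-bit EDF writer
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, channel_label: str,
                   reference_label: Optional[str] = None,
                   subject_id: Optional[str] = None) -> EegRecording:
    """Read one channel from an EDF file, re-referencing if needed.

    If the EDF stores a combined trace named ``"{channel}-{reference}"`` (or the
    bare channel with no separate reference trace), that trace is returned
    as-is; if both the channel and the reference exist as separate traces the
    output is ``channel - reference``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = raw.ch_names

    def _pick(label: str) -> Optional[str]:
        for nm in names:
            if nm.strip().upper() == label.strip().upper():
                return nm
        return None

    combined = _pick(f"{channel_label}-{reference_label}") if reference_label else None
    primary = _pick(channel_label)
    if combined is None and primary is None:
        raise KeyError(f"channel {channel_label!r} not found in {path.name} "
                       f"(available: {names})")
    if combined is not None:
        data = raw.get_data(picks=[combined], units="uV")[0]
    else:
        data = raw.get_data(picks=[primary], units="uV")[0]
        if reference_label is not None:
            ref = _pick(reference_label)
            if ref is not None:
                data = data - raw.get_data(picks=[ref], units="uV")[0]
    return EegRecording(
        subject_id=subject_id or path.stem,
        channel_label=channel_label,
        reference_label=reference_label,
        sampling_rate_hz=float(raw.info["sfreq"]),
        samples=np.asarray(data, dtype=np.float64),
    )


def _edf_ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording(recording: EegRecording, path: str | Path) -> Path:
    """Write a single-channel 16-bit EDF file (1-s data records).

    The sampling rate must be an integer number of samples per second.  The
    final partial record, if any, is zero-padded; readers therefore see the
    duration rounded up to a whole second.
    """
    path = Path(path)
    fs = recording.sampling_rate_hz
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    x = recording.samples
    n_rec = math.ceil(x.size / spr)
    pad = n_rec * spr - x.size
    if pad:
        x = np.concatenate([x, np.zeros(pad)])
    pmax = float(max(np.max(np.abs(x)), 1.0)) * (1 + 1e-6)
    pmax = float(np.ceil(pmax * 100) / 100)   # match the 2-decimal header field
    # symmetric digital range so physical = digital * pmax / 32767 exactly
    digital = np.clip(np.round(x / pmax * 32767), -32767, 32767).astype("<i2")

    label = recording.channel_label
    if recording.reference_label:
        label = f"{recording.channel_label}-{recording.reference_label}"
    buf = io.BytesIO()
    buf.write(_edf_ascii("0", 8))
    buf.write(_edf_ascii(recording.subject_id, 80))
    buf.write(_edf_ascii("Startdate 01-JAN-2001", 80))
    buf.write(_edf_ascii("01.01.01", 8))
    buf.write(_edf_ascii("00.00.00", 8))
    buf.write(_edf_ascii(256 * 2, 8))          # header bytes: global + 1 signal
    buf.write(_edf_ascii("", 44))
    buf.write(_edf_ascii(n_rec, 8))
    buf.write(_edf_ascii(1, 8))                 # record duration, s
    buf.write(_edf_ascii(1, 4))                 # number of signals
    buf.write(_edf_ascii(label, 16))
    buf.write(_edf_ascii("", 80))               # transducer
    buf.write(_edf_ascii("uV", 8))
    buf.write(_edf_ascii(f"{-pmax:.2f}"[:8], 8))
    buf.write(_edf_ascii(f"{pmax:.2f}"[:8], 8))
    buf.write(_edf_ascii(-32767, 8))
    buf.write(_edf_ascii(32767, 8))
    buf.write(_edf_ascii("", 80))               # prefiltering
    buf.write(_edf_ascii(spr, 8))
    buf.write(_edf_ascii("", 32))
    buf.write(digital.tobytes())
    path.write_bytes(buf.getvalue())
    return path


# ---------------------------------------------------------------------------
# Hypnogram reading / writing
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | Path, dialect: str = "plain_text",
                   epoch_seconds: float = 30.0,
                   token_map: Optional[dict[str, str]] = None) -> Hypnogram:
    """Parse a hypnogram file; unknown stage tokens map to UNSCORABLE.

    Dialects: ``plain_text`` (whitespace-separated W/N1/N2/N3/REM tokens),
    ``dreams`` (one numeric score per line, header lines in brackets ignored),
    ``nsrr_xml`` (Profusion XML with a ``<SleepStages>`` block).
    """
    path = Path(path)
    if dialect not in STAGE_TOKEN_MAPS:
        raise ValueError(f"unknown dialect {dialect!r}")
    mapping = token_map if token_map is not None else STAGE_TOKEN_MAPS[dialect]

    if dialect == "nsrr_xml":
        tree = ET.parse(path)
        tokens = [el.text.strip() for el in tree.iter("SleepStage")
                  if el.text and el.text.strip()]
        if not tokens:
            raise ValueError(f"no <SleepStage> entries in {path.name}")
    else:
        text = path.read_text()
        lines = [ln.strip() for ln in text.splitlines()]
        tokens = []
        for ln in lines:
            if not ln or ln.startswith("["):
                continue
            tokens.extend(ln.split())
        if not tokens:
            raise ValueError(f"empty hypnogram file {path.name}")
    stages = tuple(mapping.get(t.upper(), mapping.get(t, "UNSCORABLE"))
                   for t in tokens)
    return Hypnogram(epoch_seconds=epoch_seconds, stages=stages)


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(hypnogram.stages) + "\n")
    return path


# ---------------------------------------------------------------------------
# Event tables (TSV, one row per event; lossless round-trip)
# ---------------------------------------------------------------------------

def _flatten_event(ev) -> dict:
    from .coupling import CoupledEvent  # local import avoids a cycle

    if isinstance(ev, CoupledEvent):
        row = {"subtype": ev.subtype, "lag_s": ev.lag_s,
               "sw_channel": ev.sw_channel, "spindle_channel": ev.spindle_channel}
        row.update({f"sw_{k}": v for k, v in dataclasses.asdict(ev.slow_wave).items()})
        row.update({f"sp_{k}": v for k, v in dataclasses.asdict(ev.spindle).items()})
        return row
    return dataclasses.asdict(ev)


def events_to_frame(events: Sequence) -> pd.DataFrame:
    if len(events) == 0:
        return pd.DataFrame()
    kinds = {type(e).__name__ for e in events}
    if len(kinds) > 1:
        raise ValueError(f"event sequence is not homogeneous: {sorted(kinds)}")
    return pd.DataFrame([_flatten_event(e) for e in events])


def write_event_table(events: Sequence, path: str | Path,
                      kind: Optional[str] = None) -> Path:
    """Write events as TSV.  ``kind`` names the event class for an empty table."""
    path = Path(path)
    df = events_to_frame(events)
    if df.empty:
        from . import coupling, slow_waves, spindles
        cls = {"SlowWaveEvent": slow_waves.SlowWaveEvent,
               "SpindleEvent": spindles.SpindleEvent}.get(kind or "")
        if cls is not None:
            df = pd.DataFrame(columns=[f.name for f in dataclasses.fields(cls)])
        elif kind == "CoupledEvent":
            df = pd.DataFrame(columns=["subtype", "lag_s", "sw_channel",
                                       "spindle_channel"])
    df.to_csv(path, sep="\t", index=False)
    return path


def read_event_table(path: str | Path, kind: str) -> list:
    """Read a TSV written by :func:`write_event_table` back into events."""
    from .coupling import CoupledEvent
    from .slow_waves import SlowWaveEvent
    from .spindles import SpindleEvent

    df = pd.read_csv(path, sep="\t")
    out = []
    if kind == "SlowWaveEvent":
        for _, r in df.iterrows():
            out.append(SlowWaveEvent(**{f.name: r[f.name]
                                        for f in dataclasses.fields(SlowWaveEvent)}))
    elif kind == "SpindleEvent":
        for _, r in df.iterrows():
            out.append(SpindleEvent(**{f.name: r[f.name]
                                       for f in dataclasses.fields(SpindleEvent)}))
    elif kind == "CoupledEvent":
        for _, r in df.iterrows():
            sw = SlowWaveEvent(**{f.name: r[f"sw_{f.name}"]
                                  for f in dataclasses.fields(SlowWaveEvent)})
            sp = SpindleEvent(**{f.name: r[f"sp_{f.name}"]
                                 for f in dataclasses.fields(SpindleEvent)})
            out.append(CoupledEvent(slow_wave=sw, spindle=sp,
                                    subtype=r["subtype"], lag_s=r["lag_s"],
                                    sw_channel=r["sw_channel"],
                                    spindle_channel=r["spindle_channel"]))
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    return out
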