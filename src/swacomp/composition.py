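"""SWA composition: per-bin and per-stage late-fast/early-fast percentages.

Two distinct time axes are used and never mixed: 2-minute wall-clock bins
tile the whole recording (for the overnight histograms), while the ≥80 %
late-fast analysis concatenates the night's N2+N3 epochs into a normalized
NREM axis split into exactly 100 bins.  Bins with no coupled events carry an
undefined percentage (rendered as gaps), so they can never satisfy a
composition threshold.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .coupling import CoupledEvent
from .io_edf import Hypnogram

log = logging.getLogger(__name__)

WALLCLOCK_BIN_S = 120.0
N_NORMALIZED_BINS = 100
HIGH_LF_THRESHOLD_PCT = 80.0


@dataclass
class CompositionBin:
    t_start_s: float
    t_end_s: float
    n_lf: int
    n_ef: int

    @property
    def pct_lf(self) -> Optional[float]:
        tot = self.n_lf + self.n_ef
        if tot == 0:
            return None
        return 100.0 * self.n_lf / tot


@dataclass
class StageComposition:
    stage: str
    n_lf: int
    n_ef: int
    subject_id: str = ""
    channel_pair: str = ""

    @property
    def pct_lf(self) -> Optional[float]:
        tot = self.n_lf + self.n_ef
        if tot == 0:
            return None
        return 100.0 * self.n_lf / tot


def _subtype_counts(events: Sequence[CoupledEvent]) -> tuple[int, int]:
    n_lf = sum(1 for e in events if e.subtype == "LF_SW")
    return n_lf, len(events) - n_lf


def bin_composition(coupled: Sequence[CoupledEvent], recording_duration_s: float,
                    bin_width_s: float = WALLCLOCK_BIN_S) -> list[CompositionBin]:
    """Left-closed right-open wall-clock bins anchored at t = 0."""
    if bin_width_s <= 0:
        raise ValueError("bin width must be positive")
    n_bins = max(1, math.ceil(recording_duration_s / bin_width_s))
    counts = np.zeros((n_bins, 2), dtype=int)
    for ev in coupled:
        idx = int(ev.slow_wave.t_trough_s // bin_width_s)
        if not 0 <= idx < n_bins:
            raise ValueError("event trough outside [0, recording duration]")
        counts[idx, 0 if ev.subtype == "LF_SW" else 1] += 1
    return [CompositionBin(i * bin_width_s, (i + 1) * bin_width_s,
                           int(c[0]), int(c[1]))
            for i, c in enumerate(counts)]


def stage_percentages(coupled: Sequence[CoupledEvent], hypnogram: Hypnogram,
                      subject_id: str = "", channel_pair: str = "",
                      ) -> dict[str, StageComposition]:
    """Per-stage (N2, N3) subtype counts; events outside N2/N3 are logged out."""
    by_stage = {"N2": [], "N3": []}
    for ev in coupled:
        stage = hypnogram.stage_at(ev.slow_wave.t_trough_s)
        if stage in by_stage:
            by_stage[stage].append(ev)
        else:
            log.warning("coupled event at %.1f s falls in stage %s; excluded",
                        ev.slow_wave.t_trough_s, stage)
    out = {}
    for stage, evs in by_stage.items():
        n_lf, n_ef = _subtype_counts(evs)
        out[stage] = StageComposition(stage=stage, n_lf=n_lf, n_ef=n_ef,
                                      subject_id=subject_id,
                                      channel_pair=channel_pair)
    return out


def normalized_nrem_bins(coupled: Sequence[CoupledEvent], hypnogram: Hypnogram,
                         n_bins: int = N_NORMALIZED_BINS) -> list[CompositionBin]:
    """Composition over normalized NREM time (N2+N3 concatenated, n equal bins).

    Bin bounds are expressed in concatenated-NREM seconds.  Events whose
    trough falls outside N2/N3 epochs are excluded (with a log record).
    """
    epoch_s = hypnogram.epoch_seconds
    nrem_idx = [i for i, st in enumerate(hypnogram.stages) if st in ("N2", "N3")]
    total = len(nrem_idx) * epoch_s
    if len(nrem_idx) < 1 or total <= 0:
        raise ValueError("no NREM time in hypnogram")
    # concatenated-start time of each NREM epoch, keyed by epoch index
    cat_start = {e: k * epoch_s for k, e in enumerate(nrem_idx)}
    counts = np.zeros((n_bins, 2), dtype=int)
    for ev in coupled:
        t = ev.slow_wave.t_trough_s
        e = int(t // epoch_s)
        if e not in cat_start:
            log.warning("coupled event at %.1f s outside NREM; excluded", t)
            continue
        pos = cat_start[e] + (t - e * epoch_s)
        idx = min(int(pos / total * n_bins), n_bins - 1)
        counts[idx, 0 if ev.subtype == "LF_SW" else 1] += 1
    width = total / n_bins
    return [CompositionBin(i * width, (i + 1) * width, int(c[0]), int(c[1]))
            for i, c in enumerate(counts)]


def high_lf_bin_count(bins: Sequence[CompositionBin],
                      threshold_pct: float = HIGH_LF_THRESHOLD_PCT) -> int:
    """Number of bins whose defined late-fast percentage is >= threshold."""
    return sum(1 for b in bins
               if b.pct_lf is not None and b.pct_lf >= threshold_pct)


def plot_composition(bins: Sequence[CompositionBin], hypnogram=None, path=None):
    """Histogram of per-bin LF (blue) vs EF (red) percentages, with an
    optional hypnogram track; returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows = 2 if hypnogram is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(10, 2.2 * n_rows),
                             sharex=False, squeeze=False)
    row = 0
    if hypnogram is not None:
        order = {"W": 4, "REM": 3, "N1": 2, "N2": 1, "N3": 0, "UNSCORABLE": -1}
        t = np.arange(hypnogram.n_epochs) * hypnogram.epoch_seconds / 60
        axes[row, 0].step(t, [order[s] for s in hypnogram.stages], where="post")
        axes[row, 0].set_yticks(list(order.values()), list(order))
        axes[row, 0].set_ylabel("stage")
        row += 1
    ax = axes[row, 0]
    centers = [(b.t_start_s + b.t_end_s) / 2 / 60 for b in bins]
    width = (bins[0].t_end_s - bins[0].t_start_s) / 60 * 0.9 if bins else 1
    lf = [b.pct_lf if b.pct_lf is not None else np.nan for b in bins]
    ef = [100 - v if not np.isnan(v) else np.nan for v in lf]
    ax.bar(centers, lf, width=width, color="tab:blue", label="late-fast %")
    ax.bar(centers, ef, width=width, bottom=lf, color="tab:red",
           label="early-fast %")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("% of coupled events")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
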