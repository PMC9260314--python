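"""Per-subject and multi-subject orchestration of the SWA pipeline.

``run_subject`` executes preprocess → detect → couple → compose → ROI power
for each requested (slow-wave channel, spindle channel) pair and returns a
JSON-serializable report whose every number is recomputable from the
persisted event tables.  ``run_study`` maps a manifest of subjects onto
reports, builds group tables, and runs the stage / group comparisons.
"""
from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .composition import (bin_composition, high_lf_bin_count,
                          normalized_nrem_bins, stage_percentages)
from .coupling import classify_coupling
from .io_edf import (Hypnogram, read_hypnogram, read_recording,
                     write_event_table)
from .slow_waves import detect_slow_waves
from .spindles import detect_spindles
from .timefreq import (DEFAULT_ROIS, RoiSpec, baseline_segments,
                       morlet_tfr_batch, normalize_and_average,
                       peri_event_segments, roi_power)
from .stats import clustered_nb_count_ratio, weighted_ttest

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "detrend": {"window_s": 3.0},
    "artifact": {"threshold_uv": 900.0},
    "sw": {"min_dur_s": 0.25, "max_dur_s": 2.5},
    "spindle": {"rms_window_s": 0.5, "merge_gap_s": 0.1,
                "max_range_uv": 40.0, "outlier_sd": 8.0},
    "coupling": {"window_s": [0.2, 1.5], "reference": "onset"},
    "composition": {"bin_width_s": 120.0, "n_normalized_bins": 100,
                    "high_lf_threshold_pct": 80.0},
    "tfr": {"enabled": True, "max_events": 150, "rois": DEFAULT_ROIS},
    "hypnogram": {"dialect": "plain_text", "epoch_seconds": 30.0},
}


def load_config(path: Optional[str | Path] = None) -> dict:
    """Defaults, deep-updated by an optional YAML overlay."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        overlay = yaml.safe_load(Path(path).read_text()) or {}

        def _merge(dst, src):
            for k, v in src.items():
                if isinstance(v, dict) and isinstance(dst.get(k), dict):
                    _merge(dst[k], v)
                else:
                    dst[k] = v
        _merge(cfg, overlay)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _roi_power_by_subtype(signal: np.ndarray, fs: float, coupled, all_sw,
                          cfg: dict) -> dict:
    out = {}
    max_ev = int(cfg["tfr"]["max_events"])
    for band, subtype in (("late_fast", "LF_SW"), ("early_fast", "EF_SW")):
        events = [c.slow_wave for c in coupled if c.subtype == subtype][:max_ev]
        if not events:
            out[band] = None
            continue
        segs, kept, _ = peri_event_segments(signal, fs, events)
        bases = baseline_segments(signal, fs, kept, all_sw)
        if not segs or not bases:
            out[band] = None
            continue
        ev_maps = morlet_tfr_batch(segs, fs)
        base_maps = morlet_tfr_batch(bases, fs)
        norm = normalize_and_average(ev_maps, base_maps)
        roi = RoiSpec(name=band, **cfg["tfr"]["rois"][band])
        out[band] = roi_power(norm, roi)
    return out


def run_subject(edf_path: str | Path, hypnogram_path: str | Path,
                channel_pairs: Sequence[tuple[str, str]],
                config: Optional[dict] = None,
                subject_id: Optional[str] = None,
                out_dir: Optional[str | Path] = None) -> dict:
    """Run the full pipeline for one subject over channel pairs."""
    cfg = config or copy.deepcopy(DEFAULT_CONFIG)
    edf_path = Path(edf_path)
    hypnogram_path = Path(hypnogram_path)
    subject_id = subject_id or edf_path.stem
    if not hypnogram_path.exists():
        raise FileNotFoundError(
            f"subject {subject_id}: hypnogram not found at {hypnogram_path}")
    hyp = read_hypnogram(hypnogram_path, cfg["hypnogram"]["dialect"],
                         cfg["hypnogram"]["epoch_seconds"])
    recordings: dict[str, object] = {}

    def _rec(ch: str):
        if ch not in recordings:
            recordings[ch] = read_recording(edf_path, ch, subject_id=subject_id)
        return recordings[ch]

    report = {"subject_id": subject_id, "software_version": __version__,
              "config_hash": config_hash(cfg), "pairs": {}}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for sw_ch, sp_ch in channel_pairs:
        pair_name = f"{sw_ch}-{sp_ch}"
        rec_sw = _rec(sw_ch)
        rec_sp = _rec(sp_ch)
        sw = detect_slow_waves(rec_sw, hyp,
                               artifact_threshold_uv=cfg["artifact"]["threshold_uv"],
                               detrend_window_s=cfg["detrend"]["window_s"],
                               min_dur_s=cfg["sw"]["min_dur_s"],
                               max_dur_s=cfg["sw"]["max_dur_s"])
        spin = {band: detect_spindles(
                    rec_sp, hyp, band,
                    artifact_threshold_uv=cfg["artifact"]["threshold_uv"],
                    detrend_window_s=cfg["detrend"]["window_s"],
                    rms_window_s=cfg["spindle"]["rms_window_s"],
                    merge_gap_s=cfg["spindle"]["merge_gap_s"],
                    max_range_uv=cfg["spindle"]["max_range_uv"],
                    outlier_sd=cfg["spindle"]["outlier_sd"])
                for band in ("late_fast", "early_fast")}
        coupled, unclassified = classify_coupling(
            sw, spin["late_fast"], spin["early_fast"],
            window_s=tuple(cfg["coupling"]["window_s"]),
            reference=cfg["coupling"]["reference"],
            sw_channel=sw_ch, spindle_channel=sp_ch)
        comp_cfg = cfg["composition"]
        bins = bin_composition(coupled, rec_sw.duration_s,
                               comp_cfg["bin_width_s"])
        stage = stage_percentages(coupled, hyp, subject_id, pair_name)
        norm_bins = normalized_nrem_bins(coupled, hyp,
                                         comp_cfg["n_normalized_bins"])
        high_lf = high_lf_bin_count(norm_bins,
                                    comp_cfg["high_lf_threshold_pct"])
        roi = None
        if cfg["tfr"]["enabled"]:
            from .preprocess import sliding_detrend
            detr = sliding_detrend(rec_sw.samples, rec_sw.sampling_rate_hz,
                                   cfg["detrend"]["window_s"])
            roi = _roi_power_by_subtype(detr, rec_sw.sampling_rate_hz,
                                        coupled, sw, cfg)
        pair = {
            "n_slow_waves": len(sw),
            "n_spindles": {b: len(v) for b, v in spin.items()},
            "n_coupled": {"LF_SW": sum(1 for c in coupled if c.subtype == "LF_SW"),
                          "EF_SW": sum(1 for c in coupled if c.subtype == "EF_SW")},
            "n_unclassified": len(unclassified),
            "stage_composition": {
                st: {"n_lf": sc.n_lf, "n_ef": sc.n_ef, "pct_lf": sc.pct_lf}
                for st, sc in stage.items()},
            "high_lf_bin_count": high_lf,
            "normalized_bins": [[b.n_lf, b.n_ef] for b in norm_bins],
            "wallclock_bins": [[b.n_lf, b.n_ef] for b in bins],
            "roi_power": roi,
        }
        report["pairs"][pair_name] = pair
        if out_dir is not None:
            stem = f"{subject_id}_{pair_name}"
            write_event_table(sw, out_dir / f"{stem}_slow_waves.tsv",
                              kind="SlowWaveEvent")
            for band in spin:
                write_event_table(spin[band],
                                  out_dir / f"{stem}_spindles_{band}.tsv",
                                  kind="SpindleEvent")
            write_event_table(coupled, out_dir / f"{stem}_coupled.tsv",
                              kind="CoupledEvent")
    if out_dir is not None:
        (out_dir / f"{subject_id}_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def run_study(manifest: pd.DataFrame | str | Path,
              config: Optional[dict] = None,
              out_dir: Optional[str | Path] = None) -> dict:
    """Run every subject in a manifest and assemble group tables and stats.

    Manifest columns: subject_id, edf, hypnogram, group, channel_pairs
    (comma-separated ``SW-SP`` labels).  Per-subject failures are collected,
    not fatal.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, sep="\t")
    if manifest.empty:
        raise ValueError("empty study manifest")
    cfg = config or copy.deepcopy(DEFAULT_CONFIG)
    reports, failures = {}, {}
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        pairs = [tuple(p.split("-", 1)) for p in str(row["channel_pairs"]).split(",")]
        try:
            reports[sid] = run_subject(row["edf"], row["hypnogram"], pairs,
                                       cfg, subject_id=sid, out_dir=out_dir)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            log.error("subject %s failed: %s", sid, exc)
            failures[sid] = str(exc)

    rows = []
    groups = dict(zip(manifest["subject_id"].astype(str),
                      manifest["group"].astype(str)))
    for sid, rep in reports.items():
        for pair_name, p in rep["pairs"].items():
            sc = p["stage_composition"]
            rows.append({
                "subject_id": sid, "group": groups.get(sid, ""),
                "pair": pair_name,
                "n_slow_waves": p["n_slow_waves"],
                "n_late_fast": p["n_spindles"]["late_fast"],
                "n_early_fast": p["n_spindles"]["early_fast"],
                "n_lf_sw": p["n_coupled"]["LF_SW"],
                "n_ef_sw": p["n_coupled"]["EF_SW"],
                "n3_pct_lf": sc["N3"]["pct_lf"], "n2_pct_lf": sc["N2"]["pct_lf"],
                "n3_n_events": sc["N3"]["n_lf"] + sc["N3"]["n_ef"],
                "n2_n_events": sc["N2"]["n_lf"] + sc["N2"]["n_ef"],
                "high_lf_bin_count": p["high_lf_bin_count"],
            })
    table = pd.DataFrame(rows)
    stats_results = {}
    if not table.empty:
        for pair_name, sub in table.groupby("pair"):
            ok = sub.dropna(subset=["n3_pct_lf", "n2_pct_lf"])
            if len(ok) >= 2:
                res = weighted_ttest(ok["n3_pct_lf"], ok["n3_n_events"],
                                     ok["n2_pct_lf"], ok["n2_n_events"])
                stats_results[f"stage_pct_lf[{pair_name}]"] = res
        grp_levels = sorted(table["group"].unique())
        if len(grp_levels) == 2:
            per_subj = table.groupby(["subject_id", "group"], as_index=False)[
                "high_lf_bin_count"].mean()
            res = clustered_nb_count_ratio(
                per_subj["high_lf_bin_count"].round().astype(int),
                per_subj["group"], per_subj["subject_id"])
            stats_results["high_lf_bins[group]"] = res
    study = {"reports": reports, "failures": failures, "table": table,
             "stats": stats_results, "config_hash": config_hash(cfg)}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "study_table.tsv", sep="\t", index=False)
    return study
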