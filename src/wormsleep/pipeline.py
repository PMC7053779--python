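"""End-to-end runs: recording table in, per-stage CSVs + JSON summary out.

A run is fully described by its :class:`RunConfig`; every threshold used is
echoed into the run manifest so the summary is reproducible byte-for-byte
from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io, presets
from .bouts import bout_statistics, detect_sleep_bouts
from .events import detect_peaks
from .locomotion import compute_speed, detect_lethargus
from .trials import (classify_mobilization, classify_trial_response,
                     paired_window_test, quantify_rebound, segment_trials,
                     sleep_fraction_test)
from .types import Interval, WormRecording

log = logging.getLogger("wormsleep")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    input_path: str
    out_dir: str
    bout_preset: str = "bouts-default-10pct-2min"
    peak_preset: str = "peaks-wide"
    trial_preset: str = "trial-1min-windows"
    neuron: str = "RIS"
    channel: str = "GCaMP"
    dff_baseline: tuple | None = None   # (start_s, end_s); default: first 10% of span
    lethargus_min_duration_s: float = 1200.0
    wake_fraction_threshold: float = 0.10
    seed: int = 0
    log_level: str = "info"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Interval):
        return {"start_s": o.start, "end_s": o.end, "label": o.label}
    return str(o)


def run_pipeline(config: RunConfig) -> dict:
    """Execute extract -> behavior -> bouts -> peaks -> trials on one table."""
    logging.basicConfig(level=config.log_level.upper())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = io.validate_table(config.input_path)
    log.info("loaded %s: %d samples at %.3gs", config.input_path, len(rec),
             rec.sample_interval_s)

    summary: dict = {"input": str(config.input_path), "n_samples": len(rec)}

    # fluorescence -> ΔF/F
    from .extraction import compute_dff
    traces_out = []
    raw = rec.trace(config.neuron, config.channel)
    base = config.dff_baseline or (float(rec.time[0]),
                                   float(rec.time[0] + 0.10 * (rec.time[-1] - rec.time[0])))
    dff = compute_dff(raw, base)
    traces_out += [raw, dff]

    # behavior
    speed = None
    if "tracked_neuron" in rec.positions:
        speed = compute_speed(rec.landmark_track())
        traces_out.append(speed)
    io.write_traces(out / "traces.csv", traces_out)

    lethargus = None
    if rec.pumping is not None:
        lethargus = detect_lethargus(rec.pumping_track(),
                                     config.lethargus_min_duration_s)
        summary["lethargus"] = lethargus

    # sleep bouts over the lethargus interval (or full span)
    bout_params = presets.resolve(presets.BOUT_PRESETS, config.bout_preset)
    if speed is not None:
        span = lethargus or speed.span
        bouts = detect_sleep_bouts(speed, bout_params["smoothing"],
                                   bout_params["threshold_fraction"],
                                   bout_params["min_duration_s"], span=span)
        io.write_bouts(out / "bouts.csv", bouts)
        stats = bout_statistics(bouts, span)
        stats["bout_durations_s"] = stats["bout_durations_s"].tolist()
        summary["bouts"] = stats

    # calcium peaks
    pk = presets.resolve(presets.PEAK_PRESETS, config.peak_preset)
    peaks = detect_peaks(dff, **pk)
    io.write_peaks(out / "peaks.csv", peaks)
    summary["peaks"] = {"count": len(peaks),
                        "per_hour": len(peaks) / (dff.span.duration / 3600.0)}

    # stimulation trials
    if rec.stimulation is not None and rec.stimulation.any():
        protocol = presets.resolve(presets.TRIAL_PRESETS, config.trial_preset)
        trials = segment_trials(rec, protocol, config.neuron, config.channel,
                                wake_fraction_threshold=config.wake_fraction_threshold)
        rows = []
        for tr in trials:
            classify_trial_response(tr)
            if tr.quiescent is not None:
                classify_mobilization(tr)
            quantify_rebound(tr)
            rows.append({"trial_id": tr.trial_id,
                         "response_class": tr.response_class,
                         "mobilization_class": tr.mobilization_class,
                         "rebound_latency_s": tr.rebound.latency_s if tr.rebound else None,
                         "rebound_peak": tr.rebound.peak_max if tr.rebound else None,
                         **{f"mean_dff_{w}": m["dff"]
                            for w, m in tr.window_means.items()}})
        summary["trials"] = {
            "n": len(trials),
            "records": rows,
            "wilcoxon_dff": dataclasses.asdict(paired_window_test(trials, "dff")),
        }
        if trials and trials[0].quiescent is not None:
            summary["trials"]["fisher_sleep_fraction"] = dataclasses.asdict(
                sleep_fraction_test(trials))

    manifest = {"config": config.to_dict(),
                "presets": {"bouts": {k: (v.to_dict() if hasattr(v, "to_dict") else v)
                                      for k, v in bout_params.items()},
                            "peaks": pk}}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n")
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n")
    return summary
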