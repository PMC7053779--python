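"""Readers and writers for the pipeline's on-disk dialects.

Tables are plain CSV:

* recording table (wide): ``time_s`` (or ``time_min``), optional ``pumping``
  and ``stim`` boolean columns, landmark positions ``x_um:<name>`` /
  ``y_um:<name>`` (or ``_mm``), fluorescence ``F:<neuron>:<channel>``.
* trace table (long): ``time_s, neuron, channel, value, kind``.
* landmark table (long): ``time_s, landmark, x_um, y_um``.
* ROI track: ``frame, x, y``.
* bouts: ``t_start_s, t_end_s, label`` plus a JSON params sidecar.
* peaks: ``time_s, prominence, class``.
* aligned ensemble: ``lag_s, mean, sem, n``.

Image stacks are multi-page grayscale TIFFs read/written with tifffile.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import (AlignedEnsemble, BoutSet, FrameStack, Interval, PeakSet,
                    Trace, WormRecording)

__all__ = [
    "read_stack", "write_stack",
    "read_roi_track", "write_roi_track",
    "read_traces", "write_traces",
    "read_landmarks", "write_landmarks",
    "write_bouts", "read_bouts",
    "write_peaks", "write_ensemble",
    "write_recording", "validate_table", "read_recording",
]


def read_stack(path, channel: str = "GCaMP", dt_s: float = 5.0,
               timestamps=None, pixel_size_um: float = 1.0) -> FrameStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if timestamps is None:
        timestamps = np.arange(frames.shape[0]) * dt_s
    return FrameStack(np.asarray(frames, float), timestamps, channel,
                      pixel_size_um)


def write_stack(path, stack: FrameStack) -> None:
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32))


def read_roi_track(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require(df, ["frame", "x", "y"], path)
    df = df.sort_values("frame")
    return df[["x", "y"]].to_numpy(float)


def write_roi_track(path, centers: np.ndarray) -> None:
    centers = np.atleast_2d(centers)
    pd.DataFrame({"frame": np.arange(len(centers)),
                  "x": centers[:, 0], "y": centers[:, 1]}).to_csv(path, index=False)


def write_traces(path, traces) -> None:
    rows = []
    for tr in ([traces] if isinstance(traces, Trace) else traces):
        rows.append(pd.DataFrame({"time_s": tr.time, "neuron": tr.neuron,
                                  "channel": tr.channel, "value": tr.values,
                                  "kind": tr.kind}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list:
    df = pd.read_csv(path)
    _require(df, ["time_s", "neuron", "channel", "value", "kind"], path)
    out = []
    for (neuron, channel, kind), g in df.groupby(["neuron", "channel", "kind"],
                                                 sort=True, dropna=False):
        g = g.sort_values("time_s")
        out.append(Trace(g["time_s"].to_numpy(float), g["value"].to_numpy(float),
                         str(kind), str(neuron) if pd.notna(neuron) else "",
                         str(channel) if pd.notna(channel) else ""))
    return out


def write_landmarks(path, track) -> None:
    rows = []
    for name, xy in track.points.items():
        rows.append(pd.DataFrame({"time_s": track.time, "landmark": name,
                                  "x_um": xy[:, 0], "y_um": xy[:, 1]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_landmarks(path):
    from .types import LandmarkTrack
    df = pd.read_csv(path)
    _require(df, ["time_s", "landmark", "x_um", "y_um"], path)
    points = {}
    time = None
    for name, g in df.groupby("landmark", sort=True):
        g = g.sort_values("time_s")
        t = g["time_s"].to_numpy(float)
        if time is None:
            time = t
        elif not np.array_equal(time, t):
            raise ValueError(f"{path}: landmark {name!r} has a different time base")
        points[name] = g[["x_um", "y_um"]].to_numpy(float)
    return LandmarkTrack(time, points)


def write_bouts(path, bouts: BoutSet) -> None:
    path = Path(path)
    pd.DataFrame({"t_start_s": [iv.start for iv in bouts.intervals],
                  "t_end_s": [iv.end for iv in bouts.intervals],
                  "label": [iv.label for iv in bouts.intervals]}).to_csv(
        path, index=False)
    sidecar = path.with_suffix(path.suffix + ".params.json")
    sidecar.write_text(json.dumps(bouts.params, indent=2, sort_keys=True,
                                  default=str) + "\n")


def read_bouts(path) -> BoutSet:
    path = Path(path)
    df = pd.read_csv(path)
    _require(df, ["t_start_s", "t_end_s", "label"], path)
    params = {}
    sidecar = path.with_suffix(path.suffix + ".params.json")
    if sidecar.exists():
        params = json.loads(sidecar.read_text())
    intervals = [Interval(r.t_start_s, r.t_end_s, r.label)
                 for r in df.itertuples()]
    return BoutSet(intervals, params)


def write_peaks(path, peaks: PeakSet) -> None:
    pd.DataFrame({"time_s": peaks.peak_times, "prominence": peaks.prominences,
                  "class": peaks.width_class}).to_csv(path, index=False)


def write_ensemble(path, ens: AlignedEnsemble) -> None:
    pd.DataFrame({"lag_s": ens.lags, "mean": ens.mean, "sem": ens.sem,
                  "n": ens.n_per_lag}).to_csv(path, index=False)


# --- wide recording table -------------------------------------------------

def write_recording(path, rec: WormRecording) -> None:
    cols = {"time_s": rec.time}
    if rec.pumping is not None:
        cols["pumping"] = rec.pumping.astype(int)
    if rec.stimulation is not None:
        cols["stim"] = rec.stimulation.astype(int)
    for name, xy in sorted(rec.positions.items()):
        cols[f"x_um:{name}"] = xy[:, 0]
        cols[f"y_um:{name}"] = xy[:, 1]
    for (neuron, channel), vals in sorted(rec.fluorescence.items()):
        cols[f"F:{neuron}:{channel}"] = vals
    pd.DataFrame(cols).to_csv(path, index=False)


def validate_table(path) -> WormRecording:
    """Read + schema-check a wide recording table into a WormRecording.

    Units are normalized from the headers (``time_min`` to seconds,
    ``_mm`` positions to micrometers); rows are re-sorted by time with a
    warning; duplicated timestamps are an error naming the timestamp.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "time_s" in df.columns:
        time = df["time_s"].to_numpy(float)
    elif "time_min" in df.columns:
        time = df["time_min"].to_numpy(float) * 60.0
    else:
        raise ValueError(f"{path}: missing mandatory column time_s (or time_min)")
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 rows")
    dup = pd.Series(time).duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicated timestamp "
                         f"{time[dup.to_numpy()][0]:g}s")
    if not np.all(np.diff(time) > 0):
        warnings.warn(f"{path}: rows not sorted by time; re-sorting")
        order = np.argsort(time, kind="stable")
        df = df.iloc[order].reset_index(drop=True)
        time = time[order]

    positions: dict = {}
    fluorescence: dict = {}
    for col in df.columns:
        if col.startswith(("x_um:", "y_um:", "x_mm:", "y_mm:")):
            axis, name = col[0], col.split(":", 1)[1]
            scale = 1000.0 if col.startswith((f"{axis}_mm:",)) else 1.0
            xy = positions.setdefault(name, np.full((len(df), 2), np.nan))
            xy[:, 0 if axis == "x" else 1] = df[col].to_numpy(float) * scale
        elif col.startswith("F:"):
            _, neuron, channel = col.split(":", 2)
            vals = df[col].to_numpy(float)
            if np.isnan(vals).any():
                row = int(np.flatnonzero(np.isnan(vals))[0])
                raise ValueError(f"{path}: non-numeric value in column {col!r}, "
                                 f"row {row}")
            fluorescence[(neuron, channel)] = vals
    for name, xy in positions.items():
        if np.isnan(xy).any():
            raise ValueError(f"{path}: landmark {name!r} missing an x/y column")
    pumping = df["pumping"].to_numpy(bool) if "pumping" in df.columns else None
    stim = df["stim"].to_numpy(bool) if "stim" in df.columns else None
    return WormRecording(time, fluorescence, positions, pumping, stim,
                         meta={"source": str(path)})


read_recording = validate_table


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
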