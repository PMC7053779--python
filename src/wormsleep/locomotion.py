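"""Locomotion and behavioral-state measures from tracked landmarks.

Speed comes from the frame-to-frame displacement of a tracked landmark;
recordings without a fluorescent landmark instead use the mean absolute
frame difference of bright-field images as an activity proxy.  Movement
direction uses the nose/pharynx geometry: if the nose of the next frame has
moved away from the pharynx of the current frame the worm advanced, if it
moved closer the worm reversed; slow worms are scored sleeping outright.
Lethargus is annotated as the longest sustained non-pumping phase.
"""

from __future__ import annotations

import numpy as np

from .types import FrameStack, Interval, LandmarkTrack, PumpingTrack, Trace

__all__ = [
    "compute_speed",
    "correct_stage_drift",
    "frame_subtraction_activity",
    "classify_direction",
    "direction_intervals",
    "detect_lethargus",
]

SLEEP_SPEED_THRESHOLD_UM_S = 2.0  # per-pair speed below which a worm scores "sleeping"
LETHARGUS_MIN_DURATION_S = 20 * 60.0


def compute_speed(track: LandmarkTrack, landmark: str = "tracked_neuron") -> Trace:
    """Instantaneous centroid speed in um/s.

    speed(t_i) = ||p(t_i) - p(t_i-1)|| / (t_i - t_i-1); the first sample
    repeats the second so the trace keeps the landmark track's length.
    """
    pos = track.require(landmark)
    if len(track) < 2:
        raise ValueError("need at least 2 samples to compute speed")
    dt = np.diff(track.time)
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    speed = np.empty(len(track))
    speed[1:] = step / dt
    speed[0] = speed[1]
    return Trace(track.time, speed, "speed", neuron=landmark)


def correct_stage_drift(track: LandmarkTrack,
                        reference: str = "stage_reference") -> LandmarkTrack:
    """Subtract the stage-corner displacement from every landmark.

    Manual tracking moves the microscope stage; a stationary stage corner
    recorded alongside the worm gives the displacement to undo.
    """
    ref = track.require(reference)
    drift = ref - ref[0]
    corrected = {name: xy - drift for name, xy in track.points.items()
                 if name != reference}
    corrected[reference] = ref - drift  # constant at its initial position
    return LandmarkTrack(track.time, corrected)


def frame_subtraction_activity(stack: FrameStack) -> Trace:
    """Mean absolute pixel difference between consecutive frames.

    activity(t_i) = mean |frame_i - frame_{i-1}|; the first sample repeats
    the second (same length-preserving convention as speed).
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 frames")
    frames = np.asarray(stack.frames, dtype=float)
    diffs = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2))
    activity = np.empty(len(stack))
    activity[1:] = diffs
    activity[0] = activity[1]
    return Trace(stack.timestamps, activity, "activity", channel=stack.channel)


def classify_direction(track: LandmarkTrack,
                       speed_threshold: float = SLEEP_SPEED_THRESHOLD_UM_S,
                       speed_landmark: str = "tracked_neuron",
                       smoothing_window: int | None = None) -> np.ndarray:
    """Per-frame-pair movement labels: forward / reverse / sleeping / undetermined.

    For consecutive frames i, i+1: the worm moved forward if
    ||nose(i+1) - pharynx(i)|| exceeds ||nose(i) - pharynx(i)||, reverse if it
    shrank, undetermined on an exact tie.  Pairs whose tracked-landmark speed
    falls below ``speed_threshold`` are scored sleeping regardless of
    direction.  ``smoothing_window`` (odd, e.g. 3) applies an optional
    majority vote over neighboring labels; off by default.

    Returns ``len(track) - 1`` labels; label k covers [t_k, t_{k+1}).
    """
    nose = track.require("nose")
    pharynx = track.require("pharynx")
    if len(track) < 2:
        raise ValueError("need at least 2 samples to classify direction")
    d_now = np.linalg.norm(nose[:-1] - pharynx[:-1], axis=1)
    d_next = np.linalg.norm(nose[1:] - pharynx[:-1], axis=1)
    labels = np.where(d_next > d_now, "forward",
                      np.where(d_next < d_now, "reverse", "undetermined"))
    labels = labels.astype(object)
    speed = compute_speed(track, speed_landmark).values[1:]  # per-pair speeds
    labels[speed < speed_threshold] = "sleeping"
    if smoothing_window:
        labels = _majority_vote(labels, smoothing_window)
    return np.asarray(labels, dtype=object)


def _majority_vote(labels: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    half = window // 2
    out = labels.copy()
    n = labels.size
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        vals, counts = np.unique(labels[lo:hi], return_counts=True)
        best = counts.max()
        winners = [v for v, c in zip(vals, counts) if c == best]
        out[i] = labels[i] if labels[i] in winners else winners[0]
    return out


def direction_intervals(track: LandmarkTrack, labels: np.ndarray) -> list:
    """Merge consecutive identical labels into half-open intervals."""
    if labels.size != len(track) - 1:
        raise ValueError("expected one label per consecutive frame pair")
    out = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            out.append(Interval(float(track.time[start]), float(track.time[i]),
                                str(labels[start])))
            start = i
    return out


def detect_lethargus(pumping: PumpingTrack,
                     min_duration_s: float = LETHARGUS_MIN_DURATION_S) -> Interval | None:
    """Longest sustained non-pumping phase, the behavioral mark of lethargus.

    Returns the longest contiguous non-pumping run of duration at least
    ``min_duration_s`` as a half-open interval, or None if no run qualifies.
    Brief pump pauses are excluded by the minimum duration.
    """
    quiet = ~pumping.pumping
    t = pumping.time
    dt_last = t[-1] - t[-2] if t.size > 1 else 0.0
    edges = np.append(t, t[-1] + dt_last)
    best = None
    i = 0
    n = quiet.size
    while i < n:
        if quiet[i]:
            j = i
            while j < n and quiet[j]:
                j += 1
            iv = Interval(float(edges[i]), float(edges[j]), "lethargus")
            if iv.duration >= min_duration_s and (best is None or iv.duration > best.duration):
                best = iv
            i = j
        else:
            i += 1
    return best
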