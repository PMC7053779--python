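"""Sleep-bout segmentation from speed (or activity-proxy) traces.

The long-recording rule: smooth the speed trace, min-max normalize it over
the analyzed span, and score as sleep every contiguous run of normalized
speed below a fractional threshold that lasts at least a minimum duration
(defaults: 10% and 2 min).  The complement of sleep within the span is
motion.  Short stimulation trials cannot carry a minimum-duration rule, so a
per-sample immobility proxy is used instead: a sample is quiescent when its
speed falls below a fraction of that worm's mean wake speed.
"""

from __future__ import annotations

import numpy as np

from .smoothing import smooth_trace
from .types import BoutSet, Interval, SmoothingConfig, Trace

__all__ = [
    "smooth_trace",
    "detect_sleep_bouts",
    "detect_immobility_quiescence",
    "bout_statistics",
]

DEGENERATE_RANGE = 1e-12


def _sample_edges(time: np.ndarray) -> np.ndarray:
    """Right edges for half-open per-sample intervals: sample i covers
    [t_i, t_{i+1}), the last sample extending by the final interval."""
    dt_last = time[-1] - time[-2] if time.size > 1 else 0.0
    return np.append(time, time[-1] + dt_last)


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs, stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_sleep_bouts(speed: Trace,
                       config: SmoothingConfig = SmoothingConfig("local_linear", 20),
                       threshold_fraction: float = 0.10,
                       min_duration_s: float = 120.0,
                       span: Interval | None = None) -> BoutSet:
    """Segment a speed trace into sleep and motion bouts.

    ``span`` restricts the analysis (e.g. to the lethargus interval, or
    "2 h before lethargus to lethargus end"); normalization is computed over
    that span only, so the result is invariant under any multiplicative
    rescaling of the speed trace.  Thresholding is strict (<); the duration
    rule is inclusive (>= min_duration_s).
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if span is not None:
        speed = speed.crop(span)
    smoothed = smooth_trace(speed.values, config)
    lo, hi = smoothed.min(), smoothed.max()
    if hi - lo < DEGENERATE_RANGE:
        raise ValueError("degenerate trace: smoothed speed has no dynamic range, "
                         "normalization undefined")
    norm = (smoothed - lo) / (hi - lo)
    below = norm < threshold_fraction
    edges = _sample_edges(speed.time)
    intervals = []
    for i0, i1 in _runs(below):
        iv = Interval(float(edges[i0]), float(edges[i1]), "sleep")
        if iv.duration >= min_duration_s:
            intervals.append(iv)
    # motion is the complement of sleep within the analyzed span
    cursor = float(edges[0])
    motion = []
    for iv in intervals:
        if iv.start > cursor:
            motion.append(Interval(cursor, iv.start, "motion"))
        cursor = iv.end
    if cursor < float(edges[-1]):
        motion.append(Interval(cursor, float(edges[-1]), "motion"))
    params = {"smoothing": config.to_dict(),
              "threshold_fraction": threshold_fraction,
              "min_duration_s": min_duration_s,
              "span": (float(edges[0]), float(edges[-1])),
              "normalization": "min-max over analyzed span"}
    return BoutSet(intervals + motion, params)


def detect_immobility_quiescence(speed: Trace, wake_window: Interval,
                                 wake_fraction_threshold: float = 0.10) -> np.ndarray:
    """Per-sample immobility proxy for short stimulation trials.

    A sample is quiescent iff its speed is strictly below
    ``wake_fraction_threshold`` times the worm's mean speed over
    ``wake_window``.  No minimum-duration rule applies.
    """
    mask = wake_window.mask(speed.time)
    if not mask.any():
        raise ValueError("wake window contains no samples")
    wake_mean = float(speed.values[mask].mean())
    if wake_mean <= 0:
        raise ValueError("mean wake speed must be positive")
    return speed.values < wake_fraction_threshold * wake_mean


def bout_statistics(bouts: BoutSet, span: Interval) -> dict:
    """Sleep fraction, bout frequency per hour, and bout-duration summary."""
    if span.duration <= 0:
        raise ValueError("empty span")
    sleep = bouts.sleep
    for iv in sleep:
        if iv.start < span.start - 1e-9 or iv.end > span.end + 1e-9:
            raise ValueError(f"bout {iv} outside span {span}")
    durations = np.array([iv.duration for iv in sleep], dtype=float)
    total = float(durations.sum())
    return {
        "sleep_fraction": total / span.duration,
        "bout_frequency_per_h": len(sleep) / (span.duration / 3600.0),
        "mean_bout_duration_s": float(durations.mean()) if durations.size else float("nan"),
        "bout_durations_s": durations,
        "n_bouts": len(sleep),
    }
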