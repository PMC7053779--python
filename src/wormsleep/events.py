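"""Calcium-transient detection, event alignment, and baseline analysis.

Peaks are local maxima of the smoothed trace scored by topographic
prominence: the height of the peak above the higher of the two lowest saddle
points separating it from strictly higher terrain.  Record edges are treated
as dropping to -inf, so a peak with no higher terrain on either side (the
global maximum) gets its height above the global minimum.  Wide and narrow
transient classes differ only in smoothing span and prominence threshold and
live in a named preset registry.

Baselines for transient counting are built by excluding a top percentile
band of the trace (which removes the transients themselves), bridging the
gaps by linear interpolation, and smoothing the result with robust local
quadratic regression.
"""

from __future__ import annotations

import warnings

import numpy as np

from .smoothing import smooth_trace
from .types import (AlignedEnsemble, BaselineResult, PeakSet, SmoothingConfig,
                    Trace)
from . import fits

__all__ = [
    "detect_peaks",
    "local_maxima",
    "peak_prominences",
    "align_to_events",
    "extract_baseline",
    "count_transients",
    "fit_bout_peak_relation",
]


def local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a flat-topped plateau reports its
    leftmost sample.  Edge samples are never maxima."""
    y = np.asarray(values, float)
    n = y.size
    out = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


def peak_prominences(values: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Topographic prominence of each local maximum.

    On each side of a peak, walk outward to the nearest strictly higher
    sample; the lowest point passed is that side's saddle.  The reference
    level is the higher of the two saddles; a side with no higher terrain
    contributes no saddle, and if neither side has one the reference falls
    back to the global minimum.  Prominence = height - reference.
    """
    y = np.asarray(values, float)
    proms = np.empty(len(indices))
    for k, i in enumerate(indices):
        h = y[i]
        saddles = []
        for sl in (slice(i - 1, None, -1), slice(i + 1, None)):
            lowest = np.inf
            found = False
            for v in y[sl]:
                if v > h:
                    found = True
                    break
                lowest = min(lowest, v)
            if found:
                saddles.append(lowest)
        if saddles:
            ref = max(saddles)
        else:
            ref = y.min()
        proms[k] = h - ref
    return proms


def detect_peaks(trace: Trace, smooth_span: int = 0,
                 min_prominence: float = 0.15,
                 smooth_method: str = "local_linear",
                 width_class: str = "") -> PeakSet:
    """Detect calcium transients as prominent local maxima.

    The trace is first smoothed over ``smooth_span`` samples (0 or 1 skips
    smoothing); peaks are local maxima of the smoothed trace with prominence
    at least ``min_prominence``, positions reported on the smoothed trace.
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    y = trace.values
    if smooth_span and smooth_span > 1:
        y = smooth_trace(y, SmoothingConfig(smooth_method, smooth_span))
    idx = local_maxima(y)
    proms = peak_prominences(y, idx)
    keep = proms >= min_prominence
    idx, proms = idx[keep], proms[keep]
    return PeakSet(idx, trace.time[idx], proms, y[idx], width_class,
                   params={"smooth_span": smooth_span,
                           "smooth_method": smooth_method,
                           "min_prominence": min_prominence})


def align_to_events(traces, event_times, window: tuple,
                    baseline_samples: int | None = None,
                    normalize: str | None = None) -> AlignedEnsemble:
    """Event-triggered ensemble of trace snippets.

    ``window`` is (before_s, after_s), both positive.  Each event contributes
    one row per trace, sampled on a common lag grid; lags outside the record
    are NaN.  With ``baseline_samples`` set, each row is re-normalized as
    ΔF/F against the mean of that many samples immediately preceding the
    event (``normalize='dff'``, the default) or baseline-subtracted
    (``normalize='subtract'``); rows with no available baseline samples are
    dropped with a warning.
    """
    if np.isscalar(getattr(traces, "time", None)) or isinstance(traces, Trace):
        traces = [traces]
    event_times = np.atleast_1d(np.asarray(event_times, float))
    if event_times.size == 0:
        raise ValueError("need at least one event")
    before, after = window
    if before <= 0 or after <= 0:
        raise ValueError("window must be positive on both sides")
    if baseline_samples is not None and normalize is None:
        normalize = "dff"

    dt = traces[0].dt
    n_before = int(round(before / dt))
    n_after = int(round(after / dt))
    lags = np.arange(-n_before, n_after + 1) * dt
    rows, used_events = [], []
    for tr in traces:
        for t_ev in event_times:
            ci = int(np.argmin(np.abs(tr.time - t_ev)))
            lo, hi = ci - n_before, ci + n_after + 1
            row = np.full(lags.size, np.nan)
            src_lo, src_hi = max(0, lo), min(len(tr), hi)
            row[src_lo - lo: src_hi - lo] = tr.values[src_lo:src_hi]
            if baseline_samples:
                b_lo = max(0, ci - baseline_samples)
                base = tr.values[b_lo:ci]
                if base.size == 0:
                    warnings.warn(f"event at t={t_ev:.3f}s has no pre-event "
                                  "baseline samples; row dropped")
                    continue
                f0 = float(base.mean())
                if normalize == "dff":
                    if f0 <= 0:
                        warnings.warn(f"event at t={t_ev:.3f}s has nonpositive "
                                      "baseline mean; row dropped")
                        continue
                    row = (row - f0) / f0
                elif normalize == "subtract":
                    row = row - f0
                else:
                    raise ValueError(f"unknown normalize mode {normalize!r}")
            rows.append(row)
            used_events.append(t_ev)
    if not rows:
        raise ValueError("no event rows survived baseline screening")
    return AlignedEnsemble(lags, np.vstack(rows), np.asarray(used_events),
                           params={"window_s": (before, after),
                                   "baseline_samples": baseline_samples,
                                   "normalize": normalize})


def extract_baseline(trace: Trace, exclusion_range: tuple = (95.0, 100.0),
                     smoothing: SmoothingConfig = SmoothingConfig(
                         "robust_local_quadratic", 0.03)) -> BaselineResult:
    """Activity baseline by percentile exclusion + robust smoothing.

    Samples whose value lies in the ``exclusion_range`` percentile band
    (strictly above the lower percentile value, up to and including the
    upper) are masked out; the gaps are bridged by linear interpolation over
    the retained samples (edge values extend), and the filled series is
    smoothed.  Percentiles use the linear-interpolation quantile convention.
    """
    lo_pct, hi_pct = exclusion_range
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError("exclusion_range must satisfy 0 <= lo < hi <= 100")
    if lo_pct == 0 and hi_pct == 100:
        raise ValueError("cannot exclude the entire percentile range")
    y = trace.values
    lo_val, hi_val = np.percentile(y, [lo_pct, hi_pct])
    excluded = (y > lo_val) & (y <= hi_val)
    retained = ~excluded
    span = smoothing.resolve_span(y.size)
    if retained.sum() < span:
        raise ValueError(f"exclusion leaves {int(retained.sum())} samples, "
                         f"fewer than the smoothing span {span}")
    idx = np.arange(y.size)
    filled = np.interp(idx, idx[retained], y[retained])
    baseline = smooth_trace(filled, smoothing)
    return BaselineResult(baseline, excluded, (float(lo_pct), float(hi_pct)),
                          params={"smoothing": smoothing.to_dict()})


def count_transients(trace: Trace, baseline: BaselineResult,
                     factor: float = 2.0) -> dict:
    """Count maximal runs where the trace is at least ``factor`` times the
    baseline; returns count and frequency per hour of recording."""
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    if baseline.baseline.size != len(trace):
        raise ValueError("baseline not aligned to trace")
    above = trace.values >= factor * baseline.baseline
    padded = np.concatenate(([0], above.view(np.int8), [0]))
    count = int((np.diff(padded) == 1).sum())
    span_h = trace.span.duration / 3600.0
    return {"count": count, "per_hour": count / span_h if span_h > 0 else float("nan"),
            "factor": factor}


def fit_bout_peak_relation(motion_bout_lengths, peak_maxima) -> "fits.FitResult":
    """Logistic fit of peak calcium maxima against preceding motion-bout
    length: y = A2 + (A1 - A2) / (1 + (x / x0)^p)."""
    x = np.asarray(motion_bout_lengths, float)
    y = np.asarray(peak_maxima, float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need at least 5 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return fits.fit_curve(x, y, "logistic")
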