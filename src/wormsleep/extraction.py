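"""Fluorescence signal extraction and normalization.

An ROI (a square window following the tracked neuron) is split into signal
and background by intensity rank: the top ``signal_fraction`` of pixels are
signal, the remainder background, and the reported value is
``mean(signal) - mean(background)``.  Traces are normalized either as
ΔF/F = (F - F0)/F0 against a baseline-window mean, or ratiometrically as
ΔR/R with R = F_GCaMP / F_reference to cancel motion and bleaching artifacts
common to both channels.
"""

from __future__ import annotations

import math

import numpy as np

from .types import FrameStack, Interval, RoiSpec, Trace

__all__ = [
    "extract_roi_signal",
    "stack_to_trace",
    "compute_dff",
    "compute_drr",
]


def _clip_roi(frame: np.ndarray, center, half_size: int) -> np.ndarray:
    h, w = frame.shape
    cx, cy = center
    x0 = max(0, int(round(cx)) - half_size)
    x1 = min(w, int(round(cx)) + half_size + 1)
    y0 = max(0, int(round(cy)) - half_size)
    y1 = min(h, int(round(cy)) + half_size + 1)
    if x0 >= x1 or y0 >= y1:
        raise ValueError(f"ROI centered at ({cx}, {cy}) lies entirely outside "
                         f"the {h}x{w} frame")
    return frame[y0:y1, x0:x1]


def extract_roi_signal(frame, roi: RoiSpec, frame_index: int = 0) -> float:
    """Background-subtracted intensity of one ROI on one frame.

    The ROI pixels are ranked by intensity (ties broken by row-major pixel
    index for determinism); the top ``ceil(signal_fraction * n)`` are signal,
    the rest background.  Returns ``mean(signal) - mean(background)``.
    """
    frame = np.asarray(frame, dtype=float)
    patch = _clip_roi(frame, roi.center_at(frame_index), roi.half_size)
    flat = patch.ravel()  # row-major order fixes the tie-break
    n = flat.size
    n_sig = math.ceil(roi.signal_fraction * n)
    if n_sig < 1:
        raise ValueError("signal_fraction selects no signal pixels")
    if n_sig >= n:
        raise ValueError("signal_fraction selects every pixel; no background remains")
    order = np.argsort(-flat, kind="stable")
    signal = flat[order[:n_sig]]
    background = flat[order[n_sig:]]
    return float(signal.mean() - background.mean())


def stack_to_trace(stack: FrameStack, roi: RoiSpec, neuron: str = "") -> Trace:
    """Apply :func:`extract_roi_signal` frame-wise over a stack."""
    if roi.centers.shape[0] not in (1, len(stack)):
        raise ValueError(
            f"ROI track length {roi.centers.shape[0]} does not match "
            f"frame count {len(stack)}")
    values = np.empty(len(stack))
    for i, frame in enumerate(stack.frames):
        try:
            values[i] = extract_roi_signal(frame, roi, frame_index=i)
        except ValueError as err:
            raise ValueError(f"frame {i}: {err}") from err
    return Trace(stack.timestamps, values, "raw_F", neuron=neuron,
                 channel=stack.channel,
                 meta={"half_size": roi.half_size,
                       "signal_fraction": roi.signal_fraction})


def _baseline_mask(trace: Trace, baseline) -> np.ndarray:
    """Resolve a baseline spec to a boolean sample mask.

    ``baseline`` is a (start_s, end_s) window, an :class:`Interval`, or a
    boolean mask (e.g. all wake samples, for the wake-mean normalization
    used in long recordings spanning wake and lethargus).
    """
    if isinstance(baseline, Interval):
        mask = baseline.mask(trace.time)
    elif isinstance(baseline, (tuple, list)) and len(baseline) == 2 \
            and np.isscalar(baseline[0]):
        mask = Interval(float(baseline[0]), float(baseline[1])).mask(trace.time)
    else:
        mask = np.asarray(baseline, dtype=bool)
        if mask.shape != trace.time.shape:
            raise ValueError("baseline mask must match trace length")
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    return mask


def compute_dff(trace: Trace, baseline) -> Trace:
    """ΔF/F(t) = (F(t) - F0) / F0 with F0 the baseline mean.

    Invariant under any multiplicative gain applied to F.  ``baseline`` may
    be a (start_s, end_s) window or a boolean mask (wake-mean mode).
    """
    if trace.kind != "raw_F":
        raise ValueError(f"compute_dff expects a raw_F trace, got {trace.kind!r}")
    mask = _baseline_mask(trace, baseline)
    f0 = float(trace.values[mask].mean())
    if f0 <= 0:
        raise ValueError(f"baseline mean {f0} must be positive")
    dff = (trace.values - f0) / f0
    return trace.replace_values(dff, kind="dFF", baseline=_describe(baseline),
                                baseline_mean=f0)


def compute_drr(gcamp: Trace, reference: Trace, baseline) -> Trace:
    """Ratiometric ΔR/R with R(t) = F_GCaMP(t) / F_reference(t).

    The reference channel is matched to the calcium time base by
    nearest-neighbor lookup; samples further than one calcium sampling
    interval from any reference sample are an error.  ΔR/R is invariant
    under any gain applied equally to both channels (bleaching, illumination
    drift).
    """
    if np.any(reference.values <= 0):
        raise ValueError("reference channel contains nonpositive samples")
    ref_vals = _match_time_base(reference, gcamp.time, max_offset=gcamp.dt)
    r = gcamp.values / ref_vals
    mask = _baseline_mask(gcamp, baseline)
    r0 = float(r[mask].mean())
    if r0 <= 0:
        raise ValueError("baseline ratio mean must be positive")
    drr = (r - r0) / r0
    return Trace(gcamp.time, drr, "dRR", gcamp.neuron,
                 f"{gcamp.channel}/{reference.channel}",
                 meta={"baseline": _describe(baseline), "baseline_ratio": r0})


def _match_time_base(trace: Trace, target_time: np.ndarray,
                     max_offset: float) -> np.ndarray:
    idx = np.searchsorted(trace.time, target_time)
    idx = np.clip(idx, 1, trace.time.size - 1)
    left, right = trace.time[idx - 1], trace.time[idx]
    use_left = np.abs(target_time - left) <= np.abs(right - target_time)
    nearest = np.where(use_left, idx - 1, idx)
    offsets = np.abs(trace.time[nearest] - target_time)
    if np.any(offsets > max_offset + 1e-9):
        k = int(np.argmax(offsets))
        raise ValueError(
            f"reference sample nearest t={target_time[k]:.3f}s is "
            f"{offsets[k]:.3f}s away (limit {max_offset:.3f}s)")
    return trace.values[nearest]


def _describe(baseline) -> object:
    if isinstance(baseline, Interval):
        return (baseline.start, baseline.end)
    if isinstance(baseline, (tuple, list)) and len(baseline) == 2 \
            and np.isscalar(baseline[0]):
        return (float(baseline[0]), float(baseline[1]))
    return "mask"
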