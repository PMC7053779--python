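"""Local polynomial regression smoothing.

Three variants are used throughout the pipeline:

* ``moving_average`` — plain centered mean.
* ``local_linear`` — degree-1 polynomial fit by tricube-weighted least
  squares in a centered window, evaluated at the window center (lowess-style).
* ``robust_local_quadratic`` — degree-2 fit with the same weighting, plus an
  iterated robustness step: residuals from the previous pass are converted to
  bisquare weights, with zero weight for residuals larger than
  ``robust_cutoff`` times the mean absolute deviation of the residuals, so
  isolated calcium transients or tracking glitches do not drag the fit.

Windows are truncated (not shifted) at the record edges, so the fit near an
edge uses fewer samples but remains centered on its target sample.
"""

from __future__ import annotations

import numpy as np

from .types import SmoothingConfig

__all__ = ["smooth_trace"]

_MAX_ROBUST_PASSES = 5
_ROBUST_TOL = 1e-12


def smooth_trace(values, config: SmoothingConfig) -> np.ndarray:
    """Smooth a 1-D series; output has the same length as the input."""
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError("values must be 1-D")
    w = config.resolve_span(y.size)  # raises if the trace is too short

    if config.method == "moving_average":
        return _moving_average(y, w)
    degree = 1 if config.method == "local_linear" else 2
    smoothed = _local_poly(y, w, degree, robust_weights=None)
    if config.method == "local_linear":
        return smoothed
    # robust iteration: global passes of residual-based reweighting
    for _ in range(_MAX_ROBUST_PASSES - 1):
        resid = y - smoothed
        mad = np.mean(np.abs(resid))
        if mad < _ROBUST_TOL:
            break
        cut = config.robust_cutoff * mad
        u = np.abs(resid) / cut
        rw = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
        new = _local_poly(y, w, degree, robust_weights=rw)
        if np.max(np.abs(new - smoothed)) < _ROBUST_TOL * max(1.0, np.max(np.abs(y))):
            smoothed = new
            break
        smoothed = new
    return smoothed


def _moving_average(y: np.ndarray, w: int) -> np.ndarray:
    half = w // 2
    out = np.empty_like(y)
    csum = np.concatenate([[0.0], np.cumsum(y)])
    n = y.size
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def _tricube(d: np.ndarray) -> np.ndarray:
    """Tricube kernel on distances normalized to the window's farthest point."""
    dmax = d.max()
    if dmax <= 0:
        return np.ones_like(d)
    u = np.clip(d / dmax, 0.0, 1.0)
    return (1.0 - u**3) ** 3


def _local_poly(y: np.ndarray, w: int, degree: int,
                robust_weights: np.ndarray | None) -> np.ndarray:
    n = y.size
    half = w // 2
    x = np.arange(n, dtype=float)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        xi = x[lo:hi] - i
        yi = y[lo:hi]
        wts = _tricube(np.abs(xi))
        if robust_weights is not None:
            wts = wts * robust_weights[lo:hi]
        pos = wts > 0
        if pos.sum() <= degree:
            # too few usable samples for the polynomial: weighted mean fallback
            if pos.any():
                out[i] = np.average(yi[pos], weights=wts[pos])
            else:
                out[i] = np.average(yi, weights=_tricube(np.abs(xi)))
            continue
        sw = np.sqrt(wts[pos])
        design = np.vander(xi[pos], degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], yi[pos] * sw, rcond=None)
        out[i] = coef[0]  # polynomial evaluated at xi = 0, the window center
    return out
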