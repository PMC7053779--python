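"""Nonlinear least-squares models for dose-response and bout-peak relations.

Three saturating models:

* ``box_lucas_1``:  y = a (1 - e^(-b x))             (rise to asymptote a)
* ``asymptotic``:   y = c - a b^x  with 0 < b < 1    (exponential approach to c)
* ``logistic``:     y = A2 + (A1 - A2) / (1 + (x/x0)^p)

Fits run :func:`scipy.optimize.curve_fit` from ten deterministic,
data-driven starting points (amplitude from the data range, rate constants
from a log-spaced grid scaled by the x range) and keep the lowest residual
sum of squares, so results are reproducible without any random seed.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .types import FitResult

__all__ = ["fit_curve", "fit_dose_response", "MODEL_FUNCS"]

_DEGENERATE_PTP = 1e-12


def _box_lucas_1(x, a, b):
    return a * (1.0 - np.exp(-b * x))


def _asymptotic(x, c, a, b):
    return c - a * np.power(b, x)


def _logistic(x, A1, A2, x0, p):
    with np.errstate(divide="ignore", invalid="ignore"):
        return A2 + (A1 - A2) / (1.0 + np.power(x / x0, p))


MODEL_FUNCS = {"box_lucas_1": _box_lucas_1, "asymptotic": _asymptotic,
               "logistic": _logistic}
_PARAM_NAMES = {"box_lucas_1": ("a", "b"), "asymptotic": ("c", "a", "b"),
                "logistic": ("A1", "A2", "x0", "p")}


def _starts(model: str, x: np.ndarray, y: np.ndarray) -> list:
    xmax = max(x.max(), 1e-9)
    xpos = x[x > 0]
    xmid = float(np.median(xpos)) if xpos.size else xmax / 2
    rate_grid = np.geomspace(0.1, 30.0, 8) / xmax
    if model == "box_lucas_1":
        a0 = y[np.argmax(x)] if abs(y[np.argmax(x)]) > 0 else (np.max(np.abs(y)) or 1.0)
        starts = [(a0, b0) for b0 in rate_grid]
        # log-linearized early-slope heuristic: y ~ a*b*x near x = 0
        small = x <= np.percentile(x, 40)
        if small.sum() >= 2 and a0 != 0:
            slope = np.polyfit(x[small], y[small], 1)[0]
            b_h = abs(slope / a0)
            if np.isfinite(b_h) and b_h > 0:
                starts.append((a0, b_h))
        starts.append((float(np.mean(y)) or 1.0, 1.0 / xmax))
        return starts[:10]
    if model == "asymptotic":
        c0 = y[np.argmax(x)]
        a0 = c0 - y[np.argmin(x)]
        if a0 == 0:
            a0 = float(np.ptp(y)) or 1.0
        return [(c0, a0, b0) for b0 in
                np.clip(np.exp(-rate_grid), 1e-6, 1 - 1e-6)][:10]
    if model == "logistic":
        a1, a2 = y[np.argmin(x)], y[np.argmax(x)]
        starts = [(a1, a2, x0, p) for x0 in (xmid / 2, xmid, 2 * xmid)
                  for p in (0.5, 1.0, 2.0)]
        starts.append((a1, a2, xmid, 4.0))
        return starts[:10]
    raise ValueError(f"unknown model {model!r}")


_BOUNDS = {
    "box_lucas_1": ([-np.inf, 1e-12], [np.inf, np.inf]),
    "asymptotic": ([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 1 - 1e-9]),
    "logistic": ([-np.inf, -np.inf, 1e-12, 1e-3], [np.inf, np.inf, np.inf, np.inf]),
}


def fit_curve(x, y, model: str) -> FitResult:
    """Multi-start least-squares fit; never raises on non-convergence
    (returns ``converged=False`` instead)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if model not in MODEL_FUNCS:
        raise ValueError(f"unknown model {model!r}; have {sorted(MODEL_FUNCS)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    names = _PARAM_NAMES[model]
    tss = float(np.sum((y - y.mean()) ** 2))
    if np.ptp(y) < _DEGENERATE_PTP:
        c = float(y.mean())
        degenerate = {"box_lucas_1": {"a": c, "b": float("nan")},
                      "asymptotic": {"c": c, "a": 0.0, "b": 0.5},
                      "logistic": {"A1": c, "A2": c,
                                   "x0": float(np.median(x[x > 0])) if (x > 0).any() else 1.0,
                                   "p": 1.0}}[model]
        return FitResult(model, degenerate, r_squared=1.0, rss=0.0,
                         converged=True, degenerate=True)

    func = MODEL_FUNCS[model]
    best = None
    for p0 in _starts(model, x, y):
        try:
            lo, hi = _BOUNDS[model]
            p0c = np.clip(p0, lo, hi)
            popt, _ = curve_fit(func, x, y, p0=p0c, bounds=(lo, hi),
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - func(x, *popt)) ** 2))
        if np.all(np.isfinite(popt)) and (best is None or rss < best[0]):
            best = (rss, popt)
    if best is None:
        return FitResult(model, {k: float("nan") for k in names},
                         r_squared=float("nan"), rss=float("nan"),
                         converged=False)
    rss, popt = best
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return FitResult(model, dict(zip(names, map(float, popt))),
                     r_squared=r2, rss=rss, converged=True)


def fit_dose_response(x, y, model: str = "box_lucas_1") -> FitResult:
    """Fit a rebound metric against stimulus duration.

    ``model`` is ``box_lucas_1`` or ``asymptotic``; needs >= 3 points with
    nonnegative, non-identical x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if model not in ("box_lucas_1", "asymptotic"):
        raise ValueError("dose-response model must be box_lucas_1 or asymptotic")
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired points")
    if np.any(x < 0):
        raise ValueError("stimulus durations must be nonnegative")
    if np.ptp(x) < _DEGENERATE_PTP:
        raise ValueError("all stimulus durations identical; fit undefined")
    return fit_curve(x, y, model)
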