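"""Core containers shared by all analysis stages.

Every container validates its invariants at construction time so that a
malformed recording fails loudly at the boundary rather than deep inside an
analysis loop.  Provenance (the parameters that produced a derived object)
travels with the object in a plain ``dict`` so it can be serialized into run
manifests unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Interval",
    "Trace",
    "FrameStack",
    "RoiSpec",
    "LandmarkTrack",
    "PumpingTrack",
    "WormRecording",
    "BoutSet",
    "PeakSet",
    "AlignedEnsemble",
    "BaselineResult",
    "TrialProtocol",
    "TrialRecord",
    "Rebound",
    "StatResult",
    "FitResult",
    "SmoothingConfig",
]

TRACE_KINDS = ("raw_F", "dFF", "dRR", "speed", "activity")


def _as_time(time) -> np.ndarray:
    t = np.asarray(time, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time must be a nonempty 1-D array")
    if not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    return t


@dataclass(frozen=True)
class Interval:
    """Half-open time interval [start, end) in seconds."""

    start: float
    end: float
    label: str = ""

    def __post_init__(self):
        if not self.end >= self.start:
            raise ValueError(f"interval end {self.end} precedes start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end

    def mask(self, time: np.ndarray) -> np.ndarray:
        time = np.asarray(time, float)
        return (time >= self.start) & (time < self.end)


@dataclass
class Trace:
    """A single per-sample time series.

    ``kind`` documents the units: ``raw_F`` arbitrary fluorescence units,
    ``dFF``/``dRR`` dimensionless, ``speed`` um/s, ``activity`` mean absolute
    pixel difference per pixel.  ``meta`` carries provenance such as the
    baseline window a ΔF/F trace was normalized against.
    """

    time: np.ndarray
    values: np.ndarray
    kind: str = "raw_F"
    neuron: str = ""
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_time(self.time)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.time.shape:
            raise ValueError("values and time must have equal length")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}; expected one of {TRACE_KINDS}")

    def __len__(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.time)))

    @property
    def span(self) -> Interval:
        return Interval(float(self.time[0]), float(self.time[-1]) + self.dt)

    def crop(self, interval: Interval) -> "Trace":
        m = interval.mask(self.time)
        if not m.any():
            raise ValueError("crop interval contains no samples")
        return Trace(self.time[m], self.values[m], self.kind, self.neuron,
                     self.channel, dict(self.meta))

    def replace_values(self, values, kind: str | None = None, **meta) -> "Trace":
        md = dict(self.meta)
        md.update(meta)
        return Trace(self.time.copy(), values, kind or self.kind, self.neuron,
                     self.channel, md)


@dataclass
class FrameStack:
    """A stack of 2-D intensity frames with per-frame timestamps."""

    frames: np.ndarray
    timestamps: np.ndarray
    channel: str = "GCaMP"
    pixel_size_um: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be nonnegative")
        self.timestamps = _as_time(self.timestamps)
        if self.timestamps.size != self.frames.shape[0]:
            raise ValueError("timestamps length must equal frame count")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass
class RoiSpec:
    """Square region of interest, optionally following a tracked landmark.

    ``centers`` is either a single (x, y) pixel coordinate applied to every
    frame or an (n, 2) per-frame track.  The square has side
    ``2 * half_size + 1`` and is clipped at frame edges.  ``signal_fraction``
    of the highest-intensity pixels inside the (clipped) square count as
    signal; the remainder is background.
    """

    centers: np.ndarray
    half_size: int = 5
    signal_fraction: float = 0.10

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[1] != 2:
            raise ValueError("centers must be (x, y) pairs")
        if self.half_size < 0:
            raise ValueError("half_size must be >= 0")
        if not 0.0 < self.signal_fraction < 1.0:
            raise ValueError("signal_fraction must lie in (0, 1)")

    def center_at(self, frame_index: int) -> tuple:
        if self.centers.shape[0] == 1:
            return tuple(self.centers[0])
        return tuple(self.centers[frame_index])


@dataclass
class LandmarkTrack:
    """Named 2-D landmark positions (um) over time.

    Landmarks typically present: ``tracked_neuron``, ``nose``, ``pharynx`` and
    optionally ``stage_reference`` (a stage corner used for drift correction).
    Each named landmark is either present for every sample or absent.
    """

    time: np.ndarray
    points: Mapping[str, np.ndarray]

    def __post_init__(self):
        self.time = _as_time(self.time)
        pts = {}
        for name, xy in self.points.items():
            xy = np.asarray(xy, dtype=float)
            if xy.shape != (self.time.size, 2):
                raise ValueError(
                    f"landmark {name!r} must be ({self.time.size}, 2); got {xy.shape}")
            pts[name] = xy
        self.points = pts

    def __len__(self) -> int:
        return self.time.size

    def require(self, name: str) -> np.ndarray:
        if name not in self.points:
            raise ValueError(f"landmark {name!r} missing from track "
                             f"(have {sorted(self.points)})")
        return self.points[name]


@dataclass
class PumpingTrack:
    """Boolean pharyngeal-pumping status per sample (True = pumping)."""

    time: np.ndarray
    pumping: np.ndarray

    def __post_init__(self):
        self.time = _as_time(self.time)
        self.pumping = np.asarray(self.pumping, dtype=bool)
        if self.pumping.shape != self.time.shape:
            raise ValueError("pumping and time must have equal length")


@dataclass
class WormRecording:
    """One worm's synchronized time series.

    ``fluorescence`` maps ``(neuron, channel)`` to raw-F arrays on the shared
    time base.  ``positions`` maps landmark names to (n, 2) um coordinates.
    """

    time: np.ndarray
    fluorescence: dict = field(default_factory=dict)
    positions: dict = field(default_factory=dict)
    pumping: np.ndarray | None = None
    stimulation: np.ndarray | None = None
    sample_interval_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_time(self.time)
        n = self.time.size
        for key, vals in self.fluorescence.items():
            vals = np.asarray(vals, float)
            if vals.shape != (n,):
                raise ValueError(f"fluorescence {key} length mismatch")
            self.fluorescence[key] = vals
        for name, xy in self.positions.items():
            xy = np.asarray(xy, float)
            if xy.shape != (n, 2):
                raise ValueError(f"positions {name!r} must be ({n}, 2)")
            self.positions[name] = xy
        if self.pumping is not None:
            self.pumping = np.asarray(self.pumping, bool)
            if self.pumping.shape != (n,):
                raise ValueError("pumping length mismatch")
        if self.stimulation is not None:
            self.stimulation = np.asarray(self.stimulation, bool)
            if self.stimulation.shape != (n,):
                raise ValueError("stimulation length mismatch")
        if self.sample_interval_s is None:
            self.sample_interval_s = float(np.median(np.diff(self.time)))

    def __len__(self) -> int:
        return self.time.size

    def trace(self, neuron: str, channel: str = "GCaMP") -> Trace:
        key = (neuron, channel)
        if key not in self.fluorescence:
            raise KeyError(f"no fluorescence trace for {key}; "
                           f"have {sorted(self.fluorescence)}")
        return Trace(self.time, self.fluorescence[key], "raw_F", neuron, channel)

    def landmark_track(self) -> LandmarkTrack:
        return LandmarkTrack(self.time, dict(self.positions))

    def pumping_track(self) -> PumpingTrack:
        if self.pumping is None:
            raise ValueError("recording has no pumping channel")
        return PumpingTrack(self.time, self.pumping)


@dataclass
class BoutSet:
    """Labeled sleep/motion/lethargus intervals plus the parameters that
    produced them.  Same-label intervals are disjoint and sorted."""

    intervals: list
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        by_label: dict = {}
        for iv in self.intervals:
            by_label.setdefault(iv.label, []).append(iv)
        for label, ivs in by_label.items():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping {label!r} intervals: {a} / {b}")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.start, iv.label))

    def with_label(self, label: str) -> list:
        return [iv for iv in self.intervals if iv.label == label]

    @property
    def sleep(self) -> list:
        return self.with_label("sleep")

    @property
    def motion(self) -> list:
        return self.with_label("motion")


@dataclass
class PeakSet:
    """Detected calcium transients on a (smoothed) trace."""

    peak_indices: np.ndarray
    peak_times: np.ndarray
    prominences: np.ndarray
    heights: np.ndarray
    width_class: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.prominences = np.asarray(self.prominences, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        n = self.peak_indices.size
        if not (self.peak_times.size == self.prominences.size == self.heights.size == n):
            raise ValueError("peak arrays must share length")
        if n > 1 and not np.all(np.diff(self.peak_indices) > 0):
            raise ValueError("peak indices must be sorted")

    def __len__(self) -> int:
        return self.peak_indices.size


@dataclass
class AlignedEnsemble:
    """Event-centered matrix of trace snippets.

    Rows are events, columns are lags; lags with no data (events near record
    edges, or rows dropped for lack of baseline) are NaN, never zero.
    """

    lags: np.ndarray
    rows: np.ndarray
    event_times: np.ndarray
    mean: np.ndarray = field(init=False)
    sem: np.ndarray = field(init=False)
    n_per_lag: np.ndarray = field(init=False)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, float)
        self.rows = np.atleast_2d(np.asarray(self.rows, float))
        if self.rows.shape[1] != self.lags.size:
            raise ValueError("rows must share the lag axis")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN lags
            self.n_per_lag = np.sum(np.isfinite(self.rows), axis=0)
            self.mean = np.nanmean(np.where(np.isfinite(self.rows), self.rows, np.nan), axis=0) \
                if self.rows.size else np.full(self.lags.size, np.nan)
            sd = np.nanstd(self.rows, axis=0, ddof=1)
        self.sem = np.where(self.n_per_lag > 1, sd / np.sqrt(np.maximum(self.n_per_lag, 1)), np.nan)


@dataclass
class BaselineResult:
    """Per-sample activity baseline after percentile exclusion + smoothing."""

    baseline: np.ndarray
    excluded_mask: np.ndarray
    exclusion_range: tuple
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, float)
        self.excluded_mask = np.asarray(self.excluded_mask, bool)
        if self.baseline.shape != self.excluded_mask.shape:
            raise ValueError("baseline and excluded_mask must share length")
        if not np.all(np.isfinite(self.baseline)):
            raise ValueError("baseline must be defined (finite) at every sample")


@dataclass(frozen=True)
class TrialProtocol:
    """Stimulation-trial window layout, in seconds relative to stimulation
    onset (baseline windows therefore have negative offsets)."""

    baseline: tuple
    stimulation: tuple
    recovery: tuple
    stimulus_kind: str = "optogenetic_activation"
    post_window_s: float = 180.0
    inter_trial_s: float | None = None

    def __post_init__(self):
        wins = [("baseline", self.baseline), ("stimulation", self.stimulation),
                ("recovery", self.recovery)]
        for name, (a, b) in wins:
            if not b > a:
                raise ValueError(f"{name} window must have positive length")
        ordered = sorted(wins, key=lambda w: w[1][0])
        for (_, (a1, b1)), (_, (a2, b2)) in zip(ordered, ordered[1:]):
            if a2 < b1:
                raise ValueError("protocol windows must not overlap")

    @property
    def windows(self) -> dict:
        return {"baseline": self.baseline, "stimulation": self.stimulation,
                "recovery": self.recovery}


@dataclass
class Rebound:
    """Post-inhibition rebound transient metrics."""

    latency_s: float
    peak_max: float
    onset_time_s: float


@dataclass
class TrialRecord:
    """One stimulation trial cut to protocol windows.

    ``time`` is in seconds relative to stimulation onset.  ``window_means``
    are computed only from samples strictly inside each half-open window.
    """

    trial_id: int
    onset_time_s: float
    stim_end_s: float
    time: np.ndarray
    dff: np.ndarray
    speed: np.ndarray | None = None
    quiescent: np.ndarray | None = None
    protocol: TrialProtocol | None = None
    window_means: dict = field(default_factory=dict)
    response_class: str | None = None
    mobilization_class: str | None = None
    rebound: Rebound | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.dff = np.asarray(self.dff, float)
        if self.dff.shape != self.time.shape:
            raise ValueError("dff and time must share length")
        for name in ("speed", "quiescent"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.time.shape:
                    raise ValueError(f"{name} and time must share length")
                setattr(self, name, arr)

    def window_mask(self, window) -> np.ndarray:
        if isinstance(window, str):
            window = self.protocol.windows[window]
        a, b = window
        return (self.time >= a) & (self.time < b)

    def window_values(self, window, quantity: str = "dff") -> np.ndarray:
        arr = getattr(self, quantity)
        if arr is None:
            raise ValueError(f"trial has no {quantity!r} channel")
        return np.asarray(arr, float)[self.window_mask(window)]


@dataclass
class StatResult:
    """Outcome of a hypothesis test."""

    test: str
    statistic: float
    p_value: float
    n: int
    exact: bool = False
    degenerate: bool = False
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class FitResult:
    """Outcome of a least-squares curve fit."""

    model: str
    params: dict
    r_squared: float
    rss: float
    converged: bool = True
    degenerate: bool = False
    detail: dict = field(default_factory=dict)

    def predict(self, x):
        from . import fits  # local import avoids a cycle
        return fits.MODEL_FUNCS[self.model](np.asarray(x, float), **self.params)


@dataclass(frozen=True)
class SmoothingConfig:
    """Local-regression smoothing settings.

    ``span`` is either a sample count (int >= 3) or a fraction of the trace
    length (float in (0, 1)); even counts widen to the next odd count so the
    window stays centered.  ``robust_cutoff`` (robust method only) zeroes the
    weight of samples whose residual exceeds that many multiples of the mean
    absolute deviation of the current residuals.
    """

    method: str = "local_linear"
    span: float = 20
    robust_cutoff: float = 6.0

    VALID_METHODS = ("moving_average", "local_linear", "robust_local_quadratic")

    def __post_init__(self):
        if self.method not in self.VALID_METHODS:
            raise ValueError(f"unknown smoothing method {self.method!r}")
        if isinstance(self.span, float) and 0 < self.span < 1:
            pass
        elif int(self.span) == self.span and self.span >= 3:
            pass
        else:
            raise ValueError("span must be an int >= 3 or a fraction in (0, 1)")
        if self.robust_cutoff <= 0:
            raise ValueError("robust_cutoff must be positive")

    def resolve_span(self, n: int) -> int:
        """Resolve to an odd window length for a trace of ``n`` samples."""
        if isinstance(self.span, float) and 0 < self.span < 1:
            w = max(3, round(self.span * n))
        else:
            w = int(self.span)
        if w % 2 == 0:
            w += 1
        if n <= w:
            raise ValueError(f"trace length {n} must exceed smoothing span {w}")
        return w

    def to_dict(self) -> dict:
        return {"method": self.method, "span": self.span,
                "robust_cutoff": self.robust_cutoff}
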