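"""Stimulation-trial segmentation, statistics, and rebound quantification.

A recording with a stimulation mask is cut into trials around each
stimulation epoch.  Windows (baseline / stimulation / recovery) are protocol
offsets relative to stimulation onset; per-trial ΔF/F is normalized against
that trial's own baseline window.  Response and mobilization classes
formalize the original visual trial scoring with an explicit k·SD rule that
is recorded in every output.  Rebound transients after inhibition are
quantified by onset latency (first sustained threshold crossing after
stimulation end) and peak maximum.
"""

from __future__ import annotations

import warnings

import numpy as np

from .bouts import detect_immobility_quiescence
from .fits import fit_dose_response  # noqa: F401  (re-exported trial-analysis surface)
from .stats import compare_groups, fisher_exact_2x2, wilcoxon_signed_rank  # noqa: F401
from .types import (Interval, Rebound, StatResult, Trace, TrialProtocol,
                    TrialRecord, WormRecording)

__all__ = [
    "stimulation_epochs",
    "segment_trials",
    "paired_window_test",
    "sleep_fraction_test",
    "classify_trial_response",
    "classify_mobilization",
    "quantify_rebound",
    "fit_dose_response",
    "compare_groups",
]


def stimulation_epochs(recording: WormRecording) -> list:
    """Half-open [onset, end) intervals of the stimulation mask."""
    if recording.stimulation is None:
        raise ValueError("recording has no stimulation mask")
    mask = recording.stimulation.view(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask, [0]))))
    t = recording.time
    dt = recording.sample_interval_s
    out = []
    for i0, i1 in zip(edges[::2], edges[1::2]):
        end = t[i1] if i1 < t.size else t[-1] + dt
        out.append(Interval(float(t[i0]), float(end), "stimulation"))
    for a, b in zip(out, out[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping stimulation epochs: {a} / {b}")
    return out


def segment_trials(recording: WormRecording, protocol: TrialProtocol,
                   neuron: str = "RIS", channel: str = "GCaMP",
                   speed: Trace | None = None,
                   wake_fraction_threshold: float | None = 0.10) -> list:
    """Cut one TrialRecord per stimulation epoch.

    ΔF/F is computed per trial against the protocol's baseline window.
    If the recording carries a tracked-neuron position (or ``speed`` is
    given), per-sample speed and the immobility-quiescence proxy (wake
    window = the baseline window) are attached.  Trials whose baseline or
    stimulation window is not fully covered by the recording are dropped
    with a warning.
    """
    epochs = stimulation_epochs(recording)
    fluor = recording.fluorescence.get((neuron, channel))
    if fluor is None:
        raise ValueError(f"recording lacks fluorescence for ({neuron}, {channel})")
    if speed is None and "tracked_neuron" in recording.positions:
        from .locomotion import compute_speed
        speed = compute_speed(recording.landmark_track())
    t = recording.time
    offsets = [protocol.baseline[0], protocol.stimulation[0], protocol.recovery[0]]
    ends = [protocol.baseline[1], protocol.stimulation[1], protocol.recovery[1]]
    lo_off, hi_off = min(offsets), max(max(ends),
                                       protocol.stimulation[1] + protocol.post_window_s)
    trials = []
    for k, epoch in enumerate(epochs):
        onset = epoch.start
        t_lo, t_hi = onset + lo_off, onset + hi_off
        if onset + protocol.baseline[0] < t[0] - 1e-9 \
                or onset + protocol.stimulation[1] > t[-1] + recording.sample_interval_s:
            warnings.warn(f"trial {k} at onset {onset:.1f}s not fully covered "
                          "by the recording; dropped")
            continue
        if k + 1 < len(epochs):
            t_hi = min(t_hi, epochs[k + 1].start + lo_off)
        m = (t >= t_lo - 1e-9) & (t < t_hi)
        rel_t = t[m] - onset
        base_mask = (rel_t >= protocol.baseline[0]) & (rel_t < protocol.baseline[1])
        f0 = float(fluor[m][base_mask].mean())
        if f0 <= 0:
            warnings.warn(f"trial {k}: nonpositive baseline fluorescence; dropped")
            continue
        dff = (fluor[m] - f0) / f0
        sp = qm = None
        if speed is not None:
            sp = speed.values[m]
            if wake_fraction_threshold is not None:
                sp_trace = Trace(rel_t, sp, "speed")
                qm = detect_immobility_quiescence(
                    sp_trace, Interval(*protocol.baseline),
                    wake_fraction_threshold)
        trial = TrialRecord(k, float(onset), float(epoch.end - onset),
                            rel_t, dff, sp, qm, protocol)
        trial.window_means = _window_means(trial)
        trials.append(trial)
    return trials


def _window_means(trial: TrialRecord) -> dict:
    out = {}
    for name in trial.protocol.windows:
        entry = {"dff": float(np.mean(trial.window_values(name, "dff")))}
        if trial.speed is not None:
            entry["speed"] = float(np.mean(trial.window_values(name, "speed")))
        if trial.quiescent is not None:
            q = trial.window_values(name, "quiescent")
            entry["sleep_fraction"] = float(np.mean(q)) if q.size else float("nan")
        out[name] = entry
    return out


def paired_window_test(trials: list, quantity: str = "dff",
                       window_a="baseline", window_b="stimulation") -> StatResult:
    """Wilcoxon signed-rank on per-trial window means (window_b - window_a)."""
    if quantity not in ("dff", "speed"):
        raise ValueError("quantity must be 'dff' or 'speed'")
    pairs = []
    for tr in trials:
        va = tr.window_values(window_a, quantity)
        vb = tr.window_values(window_b, quantity)
        if va.size and vb.size:
            pairs.append((float(va.mean()), float(vb.mean())))
    if len(pairs) < 2:
        raise ValueError("need at least 2 trials with both windows")
    a, b = np.asarray(pairs).T
    return wilcoxon_signed_rank(b - a)


def sleep_fraction_test(trials: list, window_a="baseline",
                        window_b="stimulation") -> StatResult:
    """Fisher's exact test on pooled quiescent/mobile frame counts of two
    windows."""
    counts = np.zeros((2, 2), dtype=int)
    for tr in trials:
        if tr.quiescent is None:
            raise ValueError("trials lack quiescence booleans")
        for row, win in enumerate((window_a, window_b)):
            q = tr.window_values(win, "quiescent").astype(bool)
            counts[row, 0] += int(q.sum())
            counts[row, 1] += int((~q).sum())
    if counts.sum(axis=1).min() == 0:
        raise ValueError("a window contributed no samples")
    return fisher_exact_2x2(counts)


def classify_trial_response(trial: TrialRecord, k: float = 2.0) -> str:
    """activating / inhibiting / nonresponsive by the k·SD-of-baseline rule.

    Δ = mean(stimulation ΔF/F) - mean(baseline ΔF/F); the trial is
    activating when Δ > k·SD(baseline), inhibiting when Δ < -k·SD(baseline),
    else nonresponsive.
    """
    base = trial.window_values("baseline", "dff")
    if base.size < 5:
        raise ValueError("baseline window needs at least 5 samples")
    stim = trial.window_values("stimulation", "dff")
    delta = float(stim.mean() - base.mean())
    sd = float(base.std(ddof=1))
    if delta > k * sd:
        cls = "activating"
    elif delta < -k * sd:
        cls = "inhibiting"
    else:
        cls = "nonresponsive"
    trial.response_class = cls
    return cls


def classify_mobilization(trial: TrialRecord,
                          post_window_s: float | None = None) -> str:
    """mobilizing / nonmobilizing / n/a from post-stimulus quiescence.

    Nonmobilizing iff any quiescent sample occurs within ``post_window_s``
    after stimulation end; n/a when the recording truncates the window.
    """
    if trial.quiescent is None:
        raise ValueError("trial lacks quiescence booleans")
    if post_window_s is None:
        post_window_s = trial.protocol.post_window_s if trial.protocol else 180.0
    t0, t1 = trial.stim_end_s, trial.stim_end_s + post_window_s
    dt = float(np.median(np.diff(trial.time)))
    if trial.time[-1] + dt < t1 - 1e-9:
        trial.mobilization_class = "n/a"
        return "n/a"
    m = (trial.time >= t0) & (trial.time < t1)
    cls = "nonmobilizing" if np.asarray(trial.quiescent)[m].any() else "mobilizing"
    trial.mobilization_class = cls
    return cls


def quantify_rebound(trial: TrialRecord, k: float = 2.0,
                     sustain: int = 2) -> Rebound | None:
    """Post-inhibition rebound transient, or None for non-responders.

    Onset is the first time at or after stimulation end where ΔF/F exceeds
    mean(baseline) + k·SD(baseline) for at least ``sustain`` consecutive
    samples; the search starts at the last stimulation sample so a rebound
    already rising there gets latency 0 (clamped).  Peak max is the largest
    ΔF/F between onset and the first return below threshold.
    """
    base = trial.window_values("baseline", "dff")
    thr = float(base.mean() + k * base.std(ddof=1))
    dt = float(np.median(np.diff(trial.time)))
    search = trial.time >= trial.stim_end_s - dt - 1e-9
    idx = np.flatnonzero(search)
    if idx.size == 0:
        return None
    above = trial.dff[idx] > thr
    onset_pos = None
    run = 0
    for j, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= max(1, sustain):
            onset_pos = j - run + 1
            break
    if onset_pos is None:
        trial.rebound = None
        return None
    onset_i = idx[onset_pos]
    onset_t = float(trial.time[onset_i])
    # peak: from onset until first sample back below threshold
    end_i = onset_i
    while end_i < trial.time.size and trial.dff[end_i] > thr:
        end_i += 1
    peak = float(trial.dff[onset_i:end_i].max())
    reb = Rebound(latency_s=max(0.0, onset_t - trial.stim_end_s),
                  peak_max=peak, onset_time_s=onset_t)
    trial.rebound = reb
    return reb
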