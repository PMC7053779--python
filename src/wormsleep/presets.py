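"""Named parameter registries mirroring the published per-figure variants.

Every preset resolves to explicit parameters that are serialized into output
provenance; nothing downstream depends on the preset name itself.
"""

from __future__ import annotations

from .types import SmoothingConfig, TrialProtocol

SMOOTHING_PRESETS = {
    # first-degree local regression over 20 time points (long recordings)
    "linear-20": SmoothingConfig("local_linear", 20),
    # robust second-degree local regression over 3% of the trace
    "robust-3pct": SmoothingConfig("robust_local_quadratic", 0.03, 6.0),
    # robust second-degree local regression over 40 points
    "robust-40": SmoothingConfig("robust_local_quadratic", 40, 6.0),
}

BOUT_PRESETS = {
    # default long-recording rule: 10% normalized-speed threshold, 2 min
    "bouts-default-10pct-2min": {"smoothing": SMOOTHING_PRESETS["linear-20"],
                                 "threshold_fraction": 0.10,
                                 "min_duration_s": 120.0},
    # stricter 5%-of-maximum variant
    "bouts-5pct-2min": {"smoothing": SMOOTHING_PRESETS["linear-20"],
                        "threshold_fraction": 0.05,
                        "min_duration_s": 120.0},
    "bouts-robust-3pct-10pct-2min": {"smoothing": SMOOTHING_PRESETS["robust-3pct"],
                                     "threshold_fraction": 0.10,
                                     "min_duration_s": 120.0},
}

PEAK_PRESETS = {
    # wide sleep-associated transients
    "peaks-wide": {"smooth_span": 60, "min_prominence": 0.15,
                   "width_class": "wide"},
    # narrow transients
    "peaks-narrow": {"smooth_span": 5, "min_prominence": 0.2,
                     "width_class": "narrow"},
    # simultaneous RIS/PVC co-imaging variant
    "peaks-ris-pvc": {"smooth_span": 30, "min_prominence": 0.2,
                      "width_class": "wide"},
}

BASELINE_PRESETS = {
    # wild-type-like traces: exclude the top 5% before smoothing
    "baseline-95-100": {"exclusion_range": (95.0, 100.0),
                        "smoothing": SMOOTHING_PRESETS["robust-3pct"]},
    # high-transient traces: exclude the top 25%
    "baseline-75-100": {"exclusion_range": (75.0, 100.0),
                        "smoothing": SMOOTHING_PRESETS["robust-3pct"]},
}

TRIAL_PRESETS = {
    # 1-min windows: baseline 0-0.95 min, stimulation 1-1.95 min of the trial,
    # expressed here relative to stimulation onset
    "trial-1min-windows": TrialProtocol(baseline=(-60.0, -3.0),
                                        stimulation=(0.0, 57.0),
                                        recovery=(60.0, 117.0)),
    # short-baseline preparation (baseline 0.6-0.95 min)
    "trial-short-baseline": TrialProtocol(baseline=(-24.0, -3.0),
                                          stimulation=(0.0, 57.0),
                                          recovery=(60.0, 117.0)),
    # blue-light protocol: 3 min baseline, 18 s stimulation, 3 min recovery
    "trial-blue-light": TrialProtocol(baseline=(-180.0, -3.0),
                                      stimulation=(0.0, 18.0),
                                      recovery=(18.0, 198.0),
                                      stimulus_kind="blue_light"),
}


def resolve(registry: dict, name: str):
    try:
        return registry[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(registry)}") from None
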