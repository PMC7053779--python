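"""Seeded synthetic worm recordings with planted ground truth.

The generator emulates the statistical structure of long-term L1 lethargus
recordings: a worm sampled every few seconds for minutes to hours, a
lethargus interval marked by non-pumping, alternating forward/reverse runs
while awake, sleep bouts with near-complete immobility inside lethargus,
calcium transients in a sleep-active neuron (RIS-like) at each sleep-bout
onset (with an optional forward-command neuron, PVC-like, leading it),
slow multiplicative baseline drift plus shot-like noise, and optogenetic
trial blocks with planted activation/inhibition effects and post-inhibition
rebound transients.

Everything is deterministic per seed: one root seed, with fixed-offset
sub-streams per component (bout structure, locomotion, calcium, noise,
camera), so enabling an extra neuron or channel never perturbs the draws of
existing components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .types import FrameStack, Interval, WormRecording

__all__ = ["SyntheticConfig", "GroundTruth", "generate_recording",
           "render_stack", "generate_trial_set"]

# fixed sub-stream offsets (see module docstring)
_STREAM_BOUTS, _STREAM_LOCO, _STREAM_CA, _STREAM_NOISE, _STREAM_CAM = 1, 2, 3, 4, 5


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate a 2-h L1 recording sampled
    every 5 s with a 1-h lethargus phase."""

    # recording layout
    duration_s: float = 7200.0
    sample_interval_s: float = 5.0
    lethargus: tuple | None = (1800.0, 5400.0)
    # locomotion (um, seconds)
    wake_speed_um_s: float = 10.0        # lognormal mean of wake crawling speed
    wake_speed_sigma: float = 0.5        # lognormal shape parameter
    quiescent_jitter_um_s: float = 0.2   # residual motion during sleep bouts
    sleep_bout_mean_s: float = 300.0
    motion_bout_mean_s: float = 300.0
    bout_distribution: str = "exponential"   # or "fixed"
    min_bout_s: float = 130.0            # floor for exponential bout draws
    forward_run_mean_s: float = 30.0
    reverse_run_mean_s: float = 10.0
    heading_turn_sd_rad: float = 0.1
    nose_offset_um: float = 50.0         # nose leads the pharynx along the body axis
    stage_drift_um_s: float = 0.0        # constant-velocity stage drift if nonzero
    # calcium (GCaMP-like kinetics)
    neurons: tuple = ("RIS",)
    baseline_f: float = 100.0            # raw fluorescence baseline, a.u.
    drift_sd: float = 0.002              # per-step random-walk sd, ΔF/F units
    transient_amplitude: float = 1.0     # planted ΔF/F peak at sleep-bout onset
    transient_amplitude_cv: float = 0.2
    tau_rise_s: float = 3.0
    tau_decay_s: float = 30.0
    pvc_lead_s: float = 10.0             # PVC transient precedes the RIS one
    noise_sd: float = 0.02               # shot-like noise sd, fraction of baseline F
    reference_channel: bool = False      # add a calcium-insensitive (RFP-like) channel
    reference_f: float = 50.0
    # stimulation trials (generate_trial_set)
    stim_kind: str = "optogenetic_activation"
    trial_period_s: float = 240.0
    trial_baseline_s: float = 60.0
    stim_duration_s: float = 60.0
    stim_effect_dff: float = 0.5         # additive ΔF/F during stimulation
    rebound_amplitude: float = 0.0       # planted post-inhibition rebound peak (ΔF/F)
    rebound_latency_s: float = 60.0
    stim_immobilizes: bool = False       # worm quiesces during stimulation
    # optics (render_stack)
    frame_shape: tuple = (64, 64)
    blob_sigma_px: float = 2.0
    background: float = 10.0
    pixel_size_um: float = 1.0
    render_noise_sd: float = 0.0         # sd as a fraction of sqrt(intensity)
    camera_jitter_px: float = 1.0
    blob_gain: float = 0.05              # blob peak amplitude per unit raw F
    # reproducibility
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("duration_s", "sample_interval_s", "wake_speed_um_s",
                     "sleep_bout_mean_s", "motion_bout_mean_s", "noise_sd",
                     "drift_sd", "transient_amplitude_cv",
                     "quiescent_jitter_um_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.bout_distribution not in ("exponential", "fixed"):
            raise ValueError("bout_distribution must be 'exponential' or 'fixed'")
        if self.lethargus is not None:
            a, b = self.lethargus
            if not (0 <= a < b <= self.duration_s):
                raise ValueError("lethargus interval must lie inside the recording")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """The planted truth against which every analysis stage is scored."""

    sleep_bouts: list = field(default_factory=list)
    lethargus: Interval | None = None
    transients: dict = field(default_factory=dict)   # neuron -> [(time, amp)]
    direction_labels: np.ndarray | None = None       # per frame pair
    quiescent: np.ndarray | None = None              # per sample
    trial_effects: list = field(default_factory=list)
    dff_clean: dict = field(default_factory=dict)    # neuron -> noise-free ΔF/F

    @property
    def sleep_fraction_in_lethargus(self) -> float:
        if self.lethargus is None or self.lethargus.duration == 0:
            return float("nan")
        total = sum(iv.duration for iv in self.sleep_bouts)
        return total / self.lethargus.duration


def _snap(t: float, dt: float) -> float:
    return round(t / dt) * dt


def _plant_bouts(cfg: SyntheticConfig) -> list:
    """Alternating motion/sleep bouts filling the lethargus interval,
    boundaries snapped to the sample grid."""
    if cfg.lethargus is None:
        return []
    rng = cfg.rng(_STREAM_BOUTS)
    a, b = cfg.lethargus
    dt = cfg.sample_interval_s

    def draw(mean: float) -> float:
        if cfg.bout_distribution == "fixed":
            return mean
        return max(cfg.min_bout_s, rng.exponential(mean))

    bouts = []
    t = a
    sleeping = False  # lethargus entered moving
    while t < b:
        dur = draw(cfg.sleep_bout_mean_s if sleeping else cfg.motion_bout_mean_s)
        t_end = min(b, t + dur)
        s0, s1 = _snap(t, dt), _snap(t_end, dt)
        if sleeping and s1 - s0 >= dt:
            bouts.append(Interval(s0, s1, "sleep"))
        sleeping = not sleeping
        t = t_end
    return bouts


def _calcium_kernel(times: np.ndarray, t0: float, tau_r: float,
                    tau_d: float) -> np.ndarray:
    """Double-exponential transient normalized to unit peak amplitude."""
    s = times - t0
    k = np.where(s >= 0, np.exp(-np.maximum(s, 0) / tau_d)
                 - np.exp(-np.maximum(s, 0) / tau_r), 0.0)
    t_peak = np.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)
    peak = np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)
    return k / peak


def generate_recording(config: SyntheticConfig) -> tuple:
    """Emit one synchronized worm recording plus its planted ground truth."""
    cfg = config
    dt = cfg.sample_interval_s
    n = int(np.floor(cfg.duration_s / dt))
    if n < 3:
        raise ValueError("recording too short")
    time = np.arange(n) * dt

    sleep_bouts = _plant_bouts(cfg)
    quiescent = np.zeros(n, dtype=bool)
    for iv in sleep_bouts:
        quiescent |= iv.mask(time)

    # --- locomotion -------------------------------------------------------
    rng_loco = cfg.rng(_STREAM_LOCO)
    mu = np.log(cfg.wake_speed_um_s) - cfg.wake_speed_sigma**2 / 2
    pos = np.zeros((n, 2))
    heading = rng_loco.uniform(0, 2 * np.pi)
    run_sign, run_left = 1, 0.0
    labels = np.empty(n - 1, dtype=object)
    for i in range(1, n):
        if quiescent[i]:
            step = rng_loco.normal(0.0, cfg.quiescent_jitter_um_s * dt / np.sqrt(2),
                                   size=2)
            pos[i] = pos[i - 1] + step
            labels[i - 1] = "sleeping"
            continue
        if run_left <= 0:
            run_sign = -run_sign if run_left < 0 or i > 1 else run_sign
            mean = cfg.forward_run_mean_s if run_sign > 0 else cfg.reverse_run_mean_s
            run_left = rng_loco.exponential(mean)
        speed = rng_loco.lognormal(mu, cfg.wake_speed_sigma)
        heading += rng_loco.normal(0.0, cfg.heading_turn_sd_rad)
        u = np.array([np.cos(heading), np.sin(heading)])
        pos[i] = pos[i - 1] + run_sign * speed * dt * u
        labels[i - 1] = "forward" if run_sign > 0 else "reverse"
        run_left -= dt

    # body axis follows the instantaneous heading; rebuild per sample
    headings = np.zeros(n)
    # reconstruct headings from displacements where the worm moved, else hold
    disp = np.diff(pos, axis=0)
    ang = np.arctan2(disp[:, 1], disp[:, 0])
    headings[1:] = ang
    headings[0] = ang[0] if n > 1 else 0.0
    # during reverse runs the displacement points backward; flip to body axis
    for i in range(1, n):
        lbl = labels[i - 1]
        if lbl == "reverse":
            headings[i] = headings[i] + np.pi
        elif lbl == "sleeping":
            headings[i] = headings[i - 1]
    headings[0] = headings[1] if n > 1 else 0.0
    axis = np.stack([np.cos(headings), np.sin(headings)], axis=1)
    positions = {
        "tracked_neuron": pos,
        "pharynx": pos.copy(),
        "nose": pos + cfg.nose_offset_um * axis,
    }
    if cfg.stage_drift_um_s:
        drift = np.outer(time, [cfg.stage_drift_um_s, 0.0])
        positions = {k: v + drift for k, v in positions.items()}
        positions["stage_reference"] = drift.copy()

    # --- pumping ----------------------------------------------------------
    pumping = np.ones(n, dtype=bool)
    lethargus_iv = None
    if cfg.lethargus is not None:
        lethargus_iv = Interval(_snap(cfg.lethargus[0], dt),
                                _snap(cfg.lethargus[1], dt), "lethargus")
        pumping[lethargus_iv.mask(time)] = False

    # --- calcium ----------------------------------------------------------
    rng_ca = cfg.rng(_STREAM_CA)
    rng_noise = cfg.rng(_STREAM_NOISE)
    fluorescence = {}
    transients = {}
    dff_clean = {}
    onsets = np.array([iv.start for iv in sleep_bouts])
    for neuron in cfg.neurons:
        drift = np.cumsum(rng_ca.normal(0.0, cfg.drift_sd, size=n))
        ev_times = onsets - cfg.pvc_lead_s if neuron == "PVC" else onsets
        amps = cfg.transient_amplitude * np.clip(
            1.0 + cfg.transient_amplitude_cv * rng_ca.normal(size=ev_times.size),
            0.05, None)
        signal = drift.copy()
        planted = []
        for t0, a in zip(ev_times, amps):
            signal += a * _calcium_kernel(time, t0, cfg.tau_rise_s, cfg.tau_decay_s)
            planted.append((float(t0), float(a)))
        transients[neuron] = planted
        dff_clean[neuron] = signal
        noise = rng_noise.normal(0.0, cfg.noise_sd * cfg.baseline_f, size=n)
        fluorescence[(neuron, "GCaMP")] = cfg.baseline_f * (1.0 + signal) + noise
        if cfg.reference_channel:
            ref_noise = rng_noise.normal(0.0, cfg.noise_sd * cfg.reference_f, size=n)
            fluorescence[(neuron, "RFP")] = np.maximum(
                cfg.reference_f + ref_noise, 1e-3)

    recording = WormRecording(time, fluorescence, positions, pumping,
                              np.zeros(n, dtype=bool), dt,
                              meta={"generator": "wormsleep.synthetic",
                                    "seed": cfg.seed})
    truth = GroundTruth(sleep_bouts=sleep_bouts, lethargus=lethargus_iv,
                        transients=transients,
                        direction_labels=np.asarray(labels, dtype=object),
                        quiescent=quiescent, dff_clean=dff_clean)
    return recording, truth


def generate_trial_set(config: SyntheticConfig, n_trials: int) -> tuple:
    """Recording with ``n_trials`` stimulation blocks plus planted effects.

    Each block holds a baseline phase, a stimulation epoch with an additive
    ΔF/F effect (negative for inhibition), and a recovery phase that carries
    a planted rebound transient when ``rebound_amplitude`` > 0.
    """
    cfg = config
    if cfg.trial_baseline_s + cfg.stim_duration_s > cfg.trial_period_s:
        raise ValueError("trials overlap: baseline + stimulation exceed the "
                         "trial period")
    dt = cfg.sample_interval_s
    n = int(np.floor(n_trials * cfg.trial_period_s / dt))
    time = np.arange(n) * dt
    stim = np.zeros(n, dtype=bool)
    effects = []
    rng_ca = cfg.rng(_STREAM_CA)
    rng_noise = cfg.rng(_STREAM_NOISE)
    rng_loco = cfg.rng(_STREAM_LOCO)

    signal = np.cumsum(rng_ca.normal(0.0, cfg.drift_sd, size=n))
    quiescent = np.zeros(n, dtype=bool)
    for k in range(n_trials):
        onset = _snap(k * cfg.trial_period_s + cfg.trial_baseline_s, dt)
        end = _snap(onset + cfg.stim_duration_s, dt)
        m = (time >= onset) & (time < end)
        stim |= m
        signal[m] += cfg.stim_effect_dff
        entry = {"onset_s": float(onset), "end_s": float(end),
                 "effect_dff": float(cfg.stim_effect_dff),
                 "rebound_latency_s": None, "rebound_amplitude": None}
        if cfg.rebound_amplitude > 0:
            t_reb = _snap(end + cfg.rebound_latency_s, dt)
            kern = cfg.rebound_amplitude * _calcium_kernel(
                time, t_reb, cfg.tau_rise_s, cfg.tau_decay_s)
            signal += kern
            entry["rebound_latency_s"] = float(t_reb - end)
            entry["rebound_amplitude"] = float(cfg.rebound_amplitude)
            # peak as realized on the sampling grid (what the data contain)
            entry["rebound_peak_dff"] = float(kern.max())
        if cfg.stim_immobilizes:
            quiescent |= m
        effects.append(entry)

    noise = rng_noise.normal(0.0, cfg.noise_sd * cfg.baseline_f, size=n)
    fluor = cfg.baseline_f * (1.0 + signal) + noise

    # locomotion: steady wake crawling, optionally quiescent during stimulation
    mu = np.log(cfg.wake_speed_um_s) - cfg.wake_speed_sigma**2 / 2
    pos = np.zeros((n, 2))
    heading = rng_loco.uniform(0, 2 * np.pi)
    for i in range(1, n):
        if quiescent[i]:
            pos[i] = pos[i - 1] + rng_loco.normal(
                0.0, cfg.quiescent_jitter_um_s * dt / np.sqrt(2), size=2)
        else:
            speed = rng_loco.lognormal(mu, cfg.wake_speed_sigma)
            heading += rng_loco.normal(0.0, cfg.heading_turn_sd_rad)
            pos[i] = pos[i - 1] + speed * dt * np.array(
                [np.cos(heading), np.sin(heading)])

    recording = WormRecording(
        time, {("RIS", "GCaMP"): fluor}, {"tracked_neuron": pos},
        pumping=None, stimulation=stim, sample_interval_s=dt,
        meta={"generator": "wormsleep.synthetic.trials", "seed": cfg.seed,
              "stim_kind": cfg.stim_kind})
    truth = GroundTruth(trial_effects=effects, quiescent=quiescent,
                        dff_clean={"RIS": signal})
    return recording, truth


def render_stack(recording: WormRecording, config: SyntheticConfig,
                 neurons=None, channel: str = "GCaMP") -> tuple:
    """Render the recording as a fluorescence image stack.

    Each frame holds one Gaussian blob per neuron over a flat background,
    with blob amplitude proportional to that neuron's raw fluorescence, a
    camera centered on the tracked neuron with integer-pixel jitter, and
    optional shot-like noise.  Returns ``(FrameStack, roi_tracks)`` where
    ``roi_tracks`` maps each rendered neuron to its (n, 2) pixel positions.
    """
    cfg = config
    h, w = cfg.frame_shape
    if 6 * cfg.blob_sigma_px > min(h, w):
        raise ValueError("blob larger than frame")
    if neurons is None:
        neurons = sorted({n for (n, c) in recording.fluorescence if c == channel})
    if not neurons:
        raise ValueError(f"no {channel} traces to render")
    n = len(recording)
    rng_cam = cfg.rng(_STREAM_CAM)
    jitter = np.clip(np.rint(rng_cam.normal(0, cfg.camera_jitter_px, size=(n, 2))),
                     -3, 3)
    center = np.array([w / 2.0, h / 2.0])
    ref = recording.positions.get("tracked_neuron")
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((n, h, w))
    tracks = {nm: np.empty((n, 2)) for nm in neurons}
    two_sig2 = 2.0 * cfg.blob_sigma_px**2
    for i in range(n):
        frame = np.full((h, w), cfg.background, dtype=float)
        for nm in neurons:
            offset = np.zeros(2)
            if ref is not None and nm in recording.positions:
                offset = (recording.positions[nm][i] - ref[i]) / cfg.pixel_size_um
            px = center + offset + jitter[i]
            tracks[nm][i] = px
            amp = cfg.blob_gain * recording.fluorescence[(nm, channel)][i]
            frame += amp * np.exp(-((xx - px[0])**2 + (yy - px[1])**2) / two_sig2)
        if cfg.render_noise_sd > 0:
            frame += rng_cam.normal(0.0, cfg.render_noise_sd, size=(h, w)) \
                * np.sqrt(np.maximum(frame, 0.0))
        frames[i] = np.maximum(frame, 0.0)
    stack = FrameStack(frames, recording.time.copy(), channel,
                       cfg.pixel_size_um)
    return stack, tracks
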