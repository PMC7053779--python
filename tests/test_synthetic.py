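"""The synthetic-recording generator and its planted ground truth."""

import numpy as np
import pytest

from wormsleep import (RoiSpec, SyntheticConfig, classify_direction,
                       compute_speed, generate_recording, generate_trial_set,
                       render_stack, stack_to_trace)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SyntheticConfig(seed=42, duration_s=1800.0, lethargus=(300.0, 1500.0))
        r1, t1 = generate_recording(cfg)
        r2, t2 = generate_recording(cfg)
        np.testing.assert_array_equal(r1.time, r2.time)
        for key in r1.fluorescence:
            np.testing.assert_array_equal(r1.fluorescence[key],
                                          r2.fluorescence[key])
        for key in r1.positions:
            np.testing.assert_array_equal(r1.positions[key], r2.positions[key])
        assert [(iv.start, iv.end) for iv in t1.sleep_bouts] == \
               [(iv.start, iv.end) for iv in t2.sleep_bouts]

    def test_different_seeds_differ(self):
        r1, _ = generate_recording(SyntheticConfig(seed=1, duration_s=600.0,
                                                   lethargus=None))
        r2, _ = generate_recording(SyntheticConfig(seed=2, duration_s=600.0,
                                                   lethargus=None))
        assert not np.array_equal(r1.positions["tracked_neuron"],
                                  r2.positions["tracked_neuron"])

    def test_adding_a_neuron_keeps_existing_draws(self):
        c1 = SyntheticConfig(seed=5, duration_s=900.0, lethargus=(100.0, 800.0))
        c2 = SyntheticConfig(seed=5, duration_s=900.0, lethargus=(100.0, 800.0),
                             neurons=("RIS", "PVC"))
        r1, _ = generate_recording(c1)
        r2, _ = generate_recording(c2)
        np.testing.assert_array_equal(r1.fluorescence[("RIS", "GCaMP")],
                                      r2.fluorescence[("RIS", "GCaMP")])


class TestRecordingStructure:
    def test_seed_mandatory_and_lethargus_validated(self):
        with pytest.raises(ValueError, match="seed"):
            SyntheticConfig()
        with pytest.raises(ValueError, match="lethargus"):
            SyntheticConfig(seed=1, duration_s=100.0, lethargus=(0.0, 500.0))

    def test_pumping_marks_lethargus(self, default_worm):
        rec, truth = default_worm
        inside = truth.lethargus.mask(rec.time)
        assert not rec.pumping[inside].any()
        assert rec.pumping[~inside].all()

    def test_sleep_fraction_near_configured(self):
        fracs = []
        for seed in range(20):
            cfg = SyntheticConfig(seed=seed, duration_s=7200.0,
                                  lethargus=(600.0, 6600.0))
            _, truth = generate_recording(cfg)
            fracs.append(truth.sleep_fraction_in_lethargus)
        # equal sleep/motion mean durations -> fraction 0.5
        assert abs(np.mean(fracs) - 0.5) < 0.06

    def test_zero_noise_fluorescence_equals_planted_signal(self):
        cfg = SyntheticConfig(seed=9, duration_s=1800.0,
                              lethargus=(300.0, 1500.0), noise_sd=0.0,
                              drift_sd=0.0)
        rec, truth = generate_recording(cfg)
        f = rec.fluorescence[("RIS", "GCaMP")]
        np.testing.assert_allclose(
            f, cfg.baseline_f * (1.0 + truth.dff_clean["RIS"]), atol=1e-12)

    def test_wake_speed_marginal(self):
        cfg = SyntheticConfig(seed=13, duration_s=50_000.0, lethargus=None,
                              sample_interval_s=5.0)
        rec, truth = generate_recording(cfg)
        speed = compute_speed(rec.landmark_track()).values[1:]
        n = speed.size
        # lognormal(mean 10, sigma 0.5): SE of the mean at this n
        sd = 10.0 * np.sqrt(np.exp(0.25) - 1)
        assert abs(speed.mean() - 10.0) < 3 * sd / np.sqrt(n)

    def test_quiescent_speed_low_in_sleep_bouts(self, square_wave_worm):
        rec, truth = square_wave_worm
        speed = compute_speed(rec.landmark_track())
        assert speed.values[truth.quiescent].mean() < 1.0
        assert speed.values[~truth.quiescent].mean() > 5.0

    def test_direction_labels_match_classifier_when_sampled_fast(self):
        cfg = SyntheticConfig(seed=21, duration_s=600.0, lethargus=None,
                              sample_interval_s=1.0)
        rec, truth = generate_recording(cfg)
        labels = classify_direction(rec.landmark_track(), speed_threshold=2.0)
        agree = np.mean(labels == truth.direction_labels)
        assert agree > 0.97


class TestTransients:
    def test_ris_transients_at_sleep_bout_onsets(self, square_wave_worm):
        rec, truth = square_wave_worm
        onsets = {iv.start for iv in truth.sleep_bouts}
        assert {t for t, _ in truth.transients["RIS"]} == onsets

    def test_pvc_leads_ris(self):
        cfg = SyntheticConfig(seed=17, duration_s=3600.0,
                              lethargus=(600.0, 3000.0),
                              neurons=("RIS", "PVC"), pvc_lead_s=10.0)
        _, truth = generate_recording(cfg)
        ris = np.array([t for t, _ in truth.transients["RIS"]])
        pvc = np.array([t for t, _ in truth.transients["PVC"]])
        np.testing.assert_allclose(ris - pvc, 10.0)


class TestTrialSet:
    def test_overlapping_trials_error(self):
        cfg = SyntheticConfig(seed=1, trial_period_s=100.0,
                              trial_baseline_s=60.0, stim_duration_s=60.0)
        with pytest.raises(ValueError, match="overlap"):
            generate_trial_set(cfg, 3)

    def test_planted_effects_recorded(self):
        cfg = SyntheticConfig(seed=2, stim_effect_dff=-0.4,
                              rebound_amplitude=0.8, rebound_latency_s=30.0,
                              stim_kind="optogenetic_inhibition")
        rec, truth = generate_trial_set(cfg, 4)
        assert len(truth.trial_effects) == 4
        for e in truth.trial_effects:
            assert e["effect_dff"] == -0.4
            assert e["rebound_latency_s"] == pytest.approx(30.0)
        assert rec.stimulation.sum() > 0


class TestRenderStack:
    def test_round_trip_correlation(self):
        cfg = SyntheticConfig(seed=31, duration_s=1000.0,
                              lethargus=(100.0, 900.0), noise_sd=0.0,
                              render_noise_sd=0.0, camera_jitter_px=1.0)
        rec, truth = generate_recording(cfg)
        stack, tracks = render_stack(rec, cfg)
        trace = stack_to_trace(stack, RoiSpec(tracks["RIS"], 8, 0.1))
        planted = rec.fluorescence[("RIS", "GCaMP")]
        r = np.corrcoef(trace.values, planted)[0, 1]
        assert r > 0.99

    def test_background_only_extracts_zero(self):
        cfg = SyntheticConfig(seed=32, duration_s=100.0, lethargus=None,
                              blob_gain=0.0, noise_sd=0.0)
        rec, _ = generate_recording(cfg)
        stack, tracks = render_stack(rec, cfg)
        trace = stack_to_trace(stack, RoiSpec(tracks["RIS"], 6, 0.1))
        np.testing.assert_allclose(trace.values, 0.0, atol=1e-9)

    def test_amplitude_linearity(self):
        base = dict(duration_s=100.0, lethargus=None, noise_sd=0.0,
                    drift_sd=0.0, render_noise_sd=0.0, camera_jitter_px=0.0)
        c1 = SyntheticConfig(seed=33, **base)
        c2 = SyntheticConfig(seed=33, baseline_f=200.0, **base)
        r1, _ = generate_recording(c1)
        r2, _ = generate_recording(c2)
        s1, tr1 = render_stack(r1, c1)
        s2, tr2 = render_stack(r2, c2)
        v1 = stack_to_trace(s1, RoiSpec(tr1["RIS"], 8, 0.1)).values
        v2 = stack_to_trace(s2, RoiSpec(tr2["RIS"], 8, 0.1)).values
        np.testing.assert_allclose(v2, 2.0 * v1, rtol=0.02)

    def test_blob_larger_than_frame_errors(self):
        cfg = SyntheticConfig(seed=34, duration_s=50.0, lethargus=None,
                              frame_shape=(16, 16), blob_sigma_px=5.0)
        rec, _ = generate_recording(cfg)
        with pytest.raises(ValueError, match="blob"):
            render_stack(rec, cfg)
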