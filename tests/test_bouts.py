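"""Smoothing, sleep-bout segmentation, and bout statistics."""

import numpy as np
import pytest

from wormsleep import (Interval, SmoothingConfig, Trace, bout_statistics,
                       detect_immobility_quiescence, detect_sleep_bouts,
                       smooth_trace)

from oracles import bout_stats_bruteforce


def _ref_robust_local_quadratic(y, span, cutoff=6.0, passes=5):
    """Plain-loop reference implementation of iterated bisquare local
    quadratic regression (independent of the package's vectorized path)."""
    y = np.asarray(y, float)
    n = y.size
    half = span // 2
    rw = np.ones(n)
    fit = y.copy()
    for _ in range(passes):
        new = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            x = np.arange(lo, hi) - i
            d = np.abs(x).astype(float)
            dmax = d.max() if d.max() > 0 else 1.0
            w = (1 - np.minimum(d / dmax, 1) ** 3) ** 3 * rw[lo:hi]
            if (w > 0).sum() <= 2:
                new[i] = np.average(y[lo:hi], weights=np.maximum(w, 1e-12))
                continue
            A = np.column_stack([np.ones_like(x), x, x**2])
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(A * sw[:, None], y[lo:hi] * sw, rcond=None)
            new[i] = coef[0]
        fit = new
        resid = y - fit
        mad = np.abs(resid).mean()
        if mad < 1e-12:
            break
        u = np.abs(resid) / (cutoff * mad)
        rw = np.where(u < 1, (1 - u**2) ** 2, 0.0)
    return fit


class TestSmoothTrace:
    @pytest.mark.parametrize("method", ["moving_average", "local_linear",
                                        "robust_local_quadratic"])
    def test_constant_preserved(self, method):
        y = np.full(60, 4.2)
        out = smooth_trace(y, SmoothingConfig(method, 9))
        np.testing.assert_allclose(out, 4.2, atol=1e-12)

    def test_linear_ramp_unchanged_interior(self):
        y = np.linspace(0, 10, 100)
        out = smooth_trace(y, SmoothingConfig("local_linear", 21))
        np.testing.assert_allclose(out[10:-10], y[10:-10], atol=1e-9)

    def test_robust_rejects_isolated_spike(self):
        y = np.full(200, 1.0)
        y[100] = 100.0
        out = smooth_trace(y, SmoothingConfig("robust_local_quadratic", 21, 6.0))
        ref = _ref_robust_local_quadratic(y, 21, 6.0)
        keep = np.ones(200, bool)
        keep[95:106] = False
        np.testing.assert_allclose(out[keep], 1.0, atol=1e-3)
        np.testing.assert_allclose(out, ref, atol=1e-9)

    def test_matches_statsmodels_lowess_interior(self, rng):
        # degree-1 tricube local regression on a uniform grid is lowess
        import statsmodels.api as sm
        y = np.sin(np.linspace(0, 4, 120)) + rng.normal(0, 0.1, 120)
        x = np.arange(120.0)
        span = 15
        ours = smooth_trace(y, SmoothingConfig("local_linear", span))
        theirs = sm.nonparametric.lowess(y, x, frac=span / 120, it=0,
                                         return_sorted=False)
        np.testing.assert_allclose(ours[span:-span], theirs[span:-span],
                                   atol=1e-8)

    def test_span_validation(self):
        with pytest.raises(ValueError):
            SmoothingConfig("local_linear", 2)
        with pytest.raises(ValueError, match="exceed"):
            smooth_trace(np.ones(5), SmoothingConfig("local_linear", 9))


def _square_wave_speed(n_cycles=6, high_s=300.0, low_s=300.0, dt=5.0,
                       high=10.0, low=0.0):
    vals, t = [], []
    clock = 0.0
    for _ in range(n_cycles):
        for dur, lvl in ((high_s, high), (low_s, low)):
            k = int(dur / dt)
            vals += [lvl] * k
            t += list(clock + np.arange(k) * dt)
            clock += dur
    return Trace(np.array(t), np.array(vals), "speed")


class TestDetectSleepBouts:
    def test_square_wave_recovers_all_bouts(self):
        sp = _square_wave_speed()
        bouts = detect_sleep_bouts(sp, SmoothingConfig("local_linear", 20),
                                   0.10, 120.0)
        sleep = bouts.sleep
        assert len(sleep) == 6
        tol = 21 * 5.0  # one smoothing span
        for k, iv in enumerate(sleep):
            planted = (300.0 + k * 600.0, 600.0 + k * 600.0)
            assert abs(iv.start - planted[0]) <= tol
            assert abs(iv.end - planted[1]) <= tol

    def test_short_dip_rejected(self):
        # a 90-s immobile dip in a fast trace stays below the 2-min rule
        dt = 5.0
        vals = np.full(600, 10.0)
        vals[200:218] = 0.0  # 90 s
        sp = Trace(np.arange(600) * dt, vals, "speed")
        bouts = detect_sleep_bouts(sp, SmoothingConfig("local_linear", 4),
                                   0.10, 120.0)
        assert len(bouts.sleep) == 0

    def test_constant_trace_is_degenerate(self):
        sp = Trace(np.arange(100.0), np.full(100, 3.0), "speed")
        with pytest.raises(ValueError, match="degenerate"):
            detect_sleep_bouts(sp)

    def test_rescaling_invariance(self):
        sp = _square_wave_speed()
        b1 = detect_sleep_bouts(sp, threshold_fraction=0.10)
        sp2 = sp.replace_values(sp.values * 817.3)
        b2 = detect_sleep_bouts(sp2, threshold_fraction=0.10)
        assert [(iv.start, iv.end, iv.label) for iv in b1.intervals] == \
               [(iv.start, iv.end, iv.label) for iv in b2.intervals]

    def test_sleep_and_motion_partition_span(self):
        sp = _square_wave_speed()
        bouts = detect_sleep_bouts(sp)
        total = sum(iv.duration for iv in bouts.intervals)
        span = bouts.params["span"]
        assert total == pytest.approx(span[1] - span[0], abs=1e-9)
        # and no overlap anywhere
        ivs = sorted(bouts.intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            assert b.start >= a.end - 1e-9

    def test_no_bout_shorter_than_minimum(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            vals = np.abs(r.normal(5, 4, 800)) * (r.random(800) > 0.3)
            sp = Trace(np.arange(800) * 5.0, vals, "speed")
            try:
                bouts = detect_sleep_bouts(sp, min_duration_s=120.0)
            except ValueError:
                continue
            assert all(iv.duration >= 120.0 for iv in bouts.sleep)

    def test_params_recorded_for_provenance(self):
        bouts = detect_sleep_bouts(_square_wave_speed(),
                                   threshold_fraction=0.05)
        assert bouts.params["threshold_fraction"] == 0.05
        assert bouts.params["min_duration_s"] == 120.0
        assert bouts.params["smoothing"]["method"] == "local_linear"


class TestImmobilityQuiescence:
    def test_direct_rule(self):
        t = np.arange(6.0)
        sp = Trace(t, [10.0, 10.0, 0.9, 1.1, 10.0, 10.0], "speed")
        q = detect_immobility_quiescence(sp, Interval(4.0, 6.0), 0.10)
        assert list(q) == [False, False, True, False, False, False]

    def test_thirty_percent_threshold(self):
        t = np.arange(4.0)
        sp = Trace(t, [10.0, 10.0, 2.9, 3.1], "speed")
        q = detect_immobility_quiescence(sp, Interval(0.0, 2.0), 0.30)
        assert list(q) == [False, False, True, False]

    def test_zero_wake_speed_errors(self):
        sp = Trace(np.arange(4.0), np.zeros(4), "speed")
        with pytest.raises(ValueError, match="positive"):
            detect_immobility_quiescence(sp, Interval(0.0, 2.0), 0.10)


class TestBoutStatistics:
    def test_six_five_minute_bouts(self):
        from wormsleep import BoutSet
        ivs = [Interval(k * 600.0, k * 600.0 + 300.0, "sleep") for k in range(6)]
        stats = bout_statistics(BoutSet(ivs), Interval(0.0, 3600.0))
        assert stats["sleep_fraction"] == 0.5
        assert stats["bout_frequency_per_h"] == 6.0
        assert stats["mean_bout_duration_s"] == 300.0

    def test_no_bouts(self):
        from wormsleep import BoutSet
        stats = bout_statistics(BoutSet([]), Interval(0.0, 3600.0))
        assert stats["sleep_fraction"] == 0.0
        assert stats["bout_frequency_per_h"] == 0.0
        assert stats["bout_durations_s"].size == 0

    def test_matches_interval_arithmetic_oracle(self, rng):
        from wormsleep import BoutSet
        for _ in range(20):
            starts = np.sort(rng.uniform(0, 3000, size=rng.integers(1, 8)))
            ivs, raw = [], []
            cursor = 0.0
            for s in starts:
                s = max(s, cursor)
                e = s + rng.uniform(10, 400)
                if e > 3600:
                    break
                ivs.append(Interval(s, e, "sleep"))
                raw.append((s, e))
                cursor = e + 1.0
            if not ivs:
                continue
            stats = bout_statistics(BoutSet(ivs), Interval(0.0, 3600.0))
            want = bout_stats_bruteforce(raw, 0.0, 3600.0)
            for key, val in want.items():
                assert stats[key] == pytest.approx(val, abs=1e-12)
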