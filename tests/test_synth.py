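"""Synthetic generators: spectral consistency, round trips, reproducibility."""

import warnings

import numpy as np
import pytest
from scipy.signal import periodogram

from physiofluct import dfa, preproc, synth


def periodogram_slope(x, fmin=1e-4, fmax=0.1):
    f, p = periodogram(x)
    keep = (f >= fmin) & (f <= fmax) & (p > 0)
    return np.polyfit(np.log10(f[keep]), np.log10(p[keep]), 1)[0]


class TestScalingNoise:
    def test_same_seed_reproducible(self):
        a = synth.gen_scaling_noise(alpha=0.8, n=256, seed=3)
        b = synth.gen_scaling_noise(alpha=0.8, n=256, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self):
        a = synth.gen_scaling_noise(alpha=0.8, n=256, seed=3)
        b = synth.gen_scaling_noise(alpha=0.8, n=256, seed=4)
        assert not np.array_equal(a, b)

    def test_mean_sd_respected(self):
        x = synth.gen_scaling_noise(alpha=0.9, n=4096, mean=0.9, sd=0.05,
                                    seed=0)
        assert x.mean() == pytest.approx(0.9, abs=1e-9)
        assert x.std() == pytest.approx(0.05, abs=1e-9)

    def test_alpha_half_is_white(self):
        n = 4096
        x = synth.gen_scaling_noise(alpha=0.5, n=n, seed=1)
        xc = x - x.mean()
        r1 = np.sum(xc[1:] * xc[:-1]) / np.sum(xc**2)
        assert abs(r1) < 3 / np.sqrt(n)

    def test_dfa_recovers_alpha(self):
        x = synth.gen_scaling_noise(alpha=0.9, n=2**16, seed=7)
        F = dfa.dfa_fluct(x, np.unique(np.round(
            np.geomspace(16, 1024, 20)).astype(int)))
        fit = dfa.fit_exponent(F, 16, 1024)
        assert fit.alpha == pytest.approx(0.9, abs=0.05)

    def test_periodogram_slope_matches_minus_beta(self):
        # P(f) ~ f**-(2 alpha - 1); ensemble of 20 seeds
        alpha = 0.9
        slopes = [periodogram_slope(
            synth.gen_scaling_noise(alpha=alpha, n=2**16, seed=s))
            for s in range(20)]
        assert np.mean(slopes) == pytest.approx(-(2 * alpha - 1), abs=0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_scaling_noise(alpha=1.6, n=256, seed=0)
        with pytest.raises(ValueError):
            synth.ScalingNoiseSpec(0.8, n=32)
        with pytest.raises(ValueError):
            synth.ScalingNoiseSpec(0.8, n=256, sd=0.0)


class TestCrossoverNoise:
    def test_degenerate_crossover_statistics(self):
        # equal exponents reduce to single-regime noise statistics
        x = synth.gen_crossover_noise(0.7, 0.7, 30, 2**14, seed=2)
        F = dfa.dfa_fluct(x, np.unique(np.round(
            np.geomspace(6, 512, 20)).astype(int)))
        fit = dfa.fit_exponent(F, 6, 512)
        assert fit.alpha == pytest.approx(0.7, abs=0.1)
        assert fit.r2 > 0.97

    def test_seeds_differ(self):
        a = synth.gen_crossover_noise(1.0, 0.7, 30, 1024, seed=0)
        b = synth.gen_crossover_noise(1.0, 0.7, 30, 1024, seed=1)
        assert not np.array_equal(a, b)

    def test_invalid_s_cross_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_crossover_noise(1.0, 0.7, 5, 1024, seed=0)
        with pytest.raises(ValueError):
            synth.gen_crossover_noise(1.0, 0.7, 200, 1024, seed=0)

    def test_two_regime_recovery_ensemble(self):
        scales = np.unique(np.concatenate(
            [np.arange(6, 17), np.round(np.geomspace(18, 220, 12))]
        ).astype(int))
        fits = []
        for s in range(10):
            x = synth.gen_crossover_noise(1.0, 0.7, 30, 2**16, seed=s)
            F = dfa.dfa_fluct(x, scales)
            f1, f2 = dfa.alpha12(F, "RRI")
            fits.append((f1.alpha, f2.alpha))
        fits = np.array(fits)
        assert fits[:, 0].mean() == pytest.approx(1.0, abs=0.1)
        assert fits[:, 1].mean() == pytest.approx(0.7, abs=0.1)


class TestEventTimes:
    def test_unit_intervals(self):
        np.testing.assert_allclose(
            synth.gen_event_times(np.array([1.0, 1, 1])), [1, 2, 3])

    def test_empty(self):
        assert synth.gen_event_times(np.empty(0)).size == 0

    def test_diff_inverts_exactly(self, rng):
        iv = rng.uniform(0.5, 1.5, 200)
        t = synth.gen_event_times(iv, t0=2.0)
        np.testing.assert_allclose(np.diff(t), iv[1:], rtol=1e-12)
        assert t[0] == 2.0 + iv[0]

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_event_times(np.array([1.0, 0.0, 1.0]))


class TestPpgRoundTrip:
    def test_zero_arrivals_flat(self):
        x = synth.gen_ppg(np.empty(0), 128)
        assert np.all(x == 0)

    def test_single_arrival_detected_within_two_samples(self):
        fs = 128
        x = synth.gen_ppg(np.array([5.0]), fs, duration_s=12)
        det = preproc.detect_pulse_arrivals(
            preproc.SampledSignal(x, fs=fs))
        assert len(det) == 1
        assert abs(det.times[0] - 5.0) <= 2 / fs

    def test_train_count_and_accuracy(self, rng):
        fs = 128
        iv = np.clip(rng.normal(0.9, 0.05, 300), 0.4, 1.6)
        arr = synth.gen_event_times(iv, t0=1.0)
        x = synth.gen_ppg(arr, fs)
        det = preproc.detect_pulse_arrivals(preproc.SampledSignal(x, fs=fs))
        assert len(det) == 300
        err = np.array([np.min(np.abs(det.times - t)) for t in arr])
        assert np.max(err) <= 2 / fs

    def test_overlapping_pulses_warn(self):
        with pytest.warns(UserWarning):
            synth.gen_ppg(np.array([1.0, 1.05]), 128, duration_s=5)


class TestRespAndEeg:
    def test_flow_maxima_at_breath_times(self, rng):
        bt = synth.gen_event_times(np.clip(rng.normal(4, 0.3, 80), 2.2, 7.5))
        x = synth.gen_resp_flow(bt, 32)
        det = preproc.detect_breath_maxima(
            preproc.SampledSignal(x, fs=32))
        assert len(det) >= len(bt)
        err = np.array([np.min(np.abs(det.times - t)) for t in bt])
        assert np.max(err) <= 0.2

    def test_quarter_hz_count(self):
        bt = np.arange(2.0, 60.0, 4.0)  # 15 breaths in 60 s
        x = synth.gen_resp_flow(bt, 32, duration_s=60)
        det = preproc.detect_breath_maxima(preproc.SampledSignal(x, fs=32))
        assert len(det) == 15

    def test_eeg_constant_envelope_recovered(self):
        env = np.full(120, 7.5)
        x = synth.gen_eeg(env, 128)
        amp = preproc.eeg_alpha_amplitude(preproc.SampledSignal(x, fs=128))
        interior = amp.values[5:-5]
        assert np.max(np.abs(interior - 7.5)) / 7.5 < 0.02

    def test_eeg_envelope_round_trip(self, rng):
        env = np.clip(rng.normal(15, 4, 240), 1, None)
        x = synth.gen_eeg(env, 128)
        amp = preproc.eeg_alpha_amplitude(preproc.SampledSignal(x, fs=128))
        err = amp.values[5:-5] - env[5:-5]
        assert np.sqrt(np.mean(err**2)) / env.mean() < 0.10

    def test_zero_envelope_zero_output(self):
        x = synth.gen_eeg(np.zeros(30), 128)
        assert np.all(x == 0)

    def test_negative_envelope_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_eeg(np.array([1.0, -0.5, 1.0]), 128)


class TestSubject:
    def test_fixed_seed_identical(self):
        cfg = synth.SubjectConfig(stage_plan=[("N2", 40), ("R", 30)])
        a = synth.gen_subject(cfg, seed=9)
        b = synth.gen_subject(cfg, seed=9)
        np.testing.assert_array_equal(a.r_times, b.r_times)
        np.testing.assert_array_equal(a.pulse_times, b.pulse_times)
        np.testing.assert_array_equal(a.eeg_envelope_truth,
                                      b.eeg_envelope_truth)
        assert a.hypnogram.stages == b.hypnogram.stages

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_subject(synth.SubjectConfig(stage_plan=[]), seed=0)

    def test_short_stage_warns(self):
        cfg = synth.SubjectConfig(stage_plan=[("N2", 40), ("R", 5)])
        with pytest.warns(UserWarning):
            synth.gen_subject(cfg, seed=0)

    def test_event_sequences_strictly_increasing_and_ptt_in_window(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = synth.gen_subject(seed=4)
        assert np.all(np.diff(s.r_times) > 0)
        assert np.all(np.diff(s.pulse_times) > 0)
        assert np.all(np.diff(s.breath_times) > 0)
        ptt = s.pulse_times - s.r_times
        assert np.all((ptt > 0.1) & (ptt < 0.8))

    def test_filters_pass_nearly_all_synthetic_beats(self):
        from physiofluct.intervals import filter_intervals, intervals_from_events
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = synth.gen_subject(seed=11)
        vals, times = intervals_from_events(s.r_times)
        # raw intervals include episode-boundary gaps; only those may fail
        kept = filter_intervals(vals, times, "RRI")
        assert len(kept) >= 0.99 * vals.size
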