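import numpy as np
import pytest

from vogain import kinematics
from vogain.errors import InsufficientDataError
from vogain.kinematics import (HalfCycle, classify_profile, estimate_frequency,
                               peak_velocity_summary, segment_half_cycles,
                               spectral_peak_hz)
from vogain.preprocess import flag_artifacts, select_window

from conftest import clean_params, make_recording, sinusoid_recording


def accepted_window(rec):
    w = select_window(rec, flag_artifacts(rec))
    assert w.accepted
    return w


def full_window(rec):
    from vogain.preprocess import AnalysisWindow
    return AnalysisWindow(rec, 0, len(rec), 0, True, True)


class TestSegmentation:
    def test_pure_sinusoid_yields_alternating_one_second_half_cycles(self):
        # continuous 0.5 Hz sinusoid: 10 complete half-cycles of ~1 s over
        # the 10 s between the first and last interior zero crossings
        rec = sinusoid_recording(frequency=0.5, duration=10.5, lead=0.0)
        hcs = segment_half_cycles(full_window(rec))
        assert len(hcs) == 10
        for a, b in zip(hcs[:-1], hcs[1:]):
            assert a.direction != b.direction
        assert all(abs(hc.duration_s - 1.0) < 0.02 for hc in hcs)

    def test_constant_positive_velocity_has_no_half_cycles(self):
        rec = sinusoid_recording(frequency=0.5, duration=12.0)
        rec.head_velocity_dps[:] = 40.0
        assert segment_half_cycles(full_window(rec)) == []

    def test_hysteresis_suppresses_noise_crossings(self):
        # continuous cosine (starts and ends mid-lobe) so edge handling is
        # identical with and without noise
        quiet = sinusoid_recording(frequency=0.5, duration=21.0, lead=0.0)
        t = quiet.time_s
        quiet.head_velocity_dps = 50.0 * np.cos(np.pi * t)
        noisy = sinusoid_recording(frequency=0.5, duration=21.0, lead=0.0)
        rng = np.random.default_rng(1)
        noisy.head_velocity_dps = (50.0 * np.cos(np.pi * t)
                                   + rng.normal(0, 2.0, len(noisy)))
        n_quiet = len(segment_half_cycles(full_window(quiet), hysteresis_dps=5))
        n_noisy = len(segment_half_cycles(full_window(noisy), hysteresis_dps=5))
        assert n_quiet == 20
        assert n_noisy == n_quiet

    def test_durations_sum_bounded_by_window_duration(self):
        rec, _ = make_recording(clean_params(pacing_jitter_sd_hz=0.01,
                                             velocity_noise_sd_dps=2.0))
        w = accepted_window(rec)
        hcs = segment_half_cycles(w)
        assert sum(hc.duration_s for hc in hcs) <= w.duration_s + 1e-6


class TestFrequency:
    def test_pure_sinusoid_frequency_within_one_percent(self):
        rec = sinusoid_recording(frequency=0.75, duration=16.0, lead=1.0)
        hcs = segment_half_cycles(full_window(rec))
        assert estimate_frequency(hcs) == pytest.approx(0.75, rel=0.01)

    def test_median_robust_to_one_slow_cycle(self):
        # durations {0.5, 0.5, 0.5, 0.7} -> 1/(2*0.5) = 1.0 Hz
        hcs = [HalfCycle(0, 1, "right", 50.0, d)
               for d in (0.5, 0.5, 0.5, 0.7)]
        assert estimate_frequency(hcs) == pytest.approx(1.0)

    def test_fewer_than_two_half_cycles_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            estimate_frequency([HalfCycle(0, 1, "right", 50.0, 0.5)])

    def test_jittered_pacing_recovered_within_30_mhz(self):
        errs = []
        for seed in range(20):
            p = clean_params(pacing_jitter_sd_hz=0.01,
                             velocity_noise_sd_dps=2.0, seed=seed)
            rec, truth = make_recording(p, frequency=1.0)
            hcs = segment_half_cycles(accepted_window(rec))
            errs.append(estimate_frequency(hcs) - 1.0)
        assert max(abs(e) for e in errs) < 0.03

    def test_scale_invariance(self):
        rec = sinusoid_recording(frequency=0.5, duration=22.0, lead=1.0)
        f1 = estimate_frequency(segment_half_cycles(full_window(rec)))
        rec.head_velocity_dps = rec.head_velocity_dps * 7.0
        rec.eye_velocity_dps = rec.eye_velocity_dps * 7.0
        f2 = estimate_frequency(segment_half_cycles(full_window(rec)))
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_spectral_peak_cross_check(self):
        rec = sinusoid_recording(frequency=0.75, duration=22.0, lead=1.0)
        f = spectral_peak_hz(rec.head_velocity_dps, rec.sample_rate_hz)
        assert f == pytest.approx(0.75, abs=0.06)


class TestPeakVelocity:
    def test_sinusoid_mean_peak_matches_2pifa(self):
        # A = 15 deg at 1 Hz -> 2*pi*15 = 94.2 deg/s
        rec = sinusoid_recording(frequency=1.0, amplitude_deg=15.0,
                                 duration=12.0, lead=1.0)
        hcs = segment_half_cycles(full_window(rec))
        summary = peak_velocity_summary(hcs)
        assert summary.mean_dps == pytest.approx(2 * np.pi * 15, rel=0.01)

    def test_identical_half_cycles_have_equal_direction_means(self):
        rec = sinusoid_recording(frequency=1.0, duration=12.0, lead=1.0)
        s = peak_velocity_summary(segment_half_cycles(full_window(rec)))
        assert s.right_mean_dps == pytest.approx(s.left_mean_dps, rel=1e-6)
        assert s.mean_dps == pytest.approx(s.right_mean_dps, rel=1e-6)

    def test_simulator_peaks_inside_protocol_band_at_quarter_hz(self):
        p = clean_params()
        rec, _ = make_recording(p, frequency=0.25)
        s = peak_velocity_summary(segment_half_cycles(accepted_window(rec)))
        assert 2 * np.pi * 0.25 * 14 - 0.5 <= s.mean_dps <= 2 * np.pi * 0.25 * 18.5 + 0.5


class TestProfileClassifier:
    @pytest.mark.parametrize("profile", ["sinusoidal", "square", "jerky"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generative_label_recovery(self, profile, seed):
        p = clean_params(profile_type=profile, velocity_noise_sd_dps=2.0,
                         pacing_jitter_sd_hz=0.01, seed=seed)
        rec, _ = make_recording(p, frequency=0.5)
        report = classify_profile(accepted_window(rec))
        assert report.label == profile

    def test_report_invariants(self):
        rec, _ = make_recording(clean_params(velocity_noise_sd_dps=2.0))
        r = classify_profile(accepted_window(rec))
        assert 0 <= r.sinusoid_fit_r2 <= 1
        assert r.harmonic_distortion >= 0
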