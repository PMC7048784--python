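"""Pitch, perturbation measures, HNR and MFCC extraction."""

import numpy as np
import pytest
from scipy.fft import idct

from sitpipe.voice import (
    PitchTrack,
    estimate_pitch,
    extract_periods,
    hnr,
    jitter_measures,
    mel_log_energies,
    mfcc_frames,
    mfcc_mean,
    shimmer_measures,
    voice_summary,
)

RATE = 16000


def sine(freq, duration=1.0, rate=RATE, amp=0.8):
    t = np.arange(int(duration * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


class TestPitch:
    def test_pure_sine_200hz(self):
        track = estimate_pitch(sine(200.0), RATE)
        f0 = track.f0[track.voiced]
        assert len(f0) > 50
        assert np.all(np.abs(f0 - 200.0) < 1.0)

    def test_white_noise_mostly_unvoiced(self):
        rng = np.random.default_rng(0)
        track = estimate_pitch(rng.standard_normal(RATE), RATE)
        assert (~track.voiced).mean() >= 0.95

    def test_harmonic_tone_no_octave_error(self):
        t = np.arange(RATE) / RATE
        wave = sum(np.sin(2 * np.pi * 120 * k * t) / k for k in range(1, 6))
        track = estimate_pitch(wave, RATE)
        f0 = np.nanmedian(track.f0)
        assert f0 == pytest.approx(120.0, abs=1.0)

    @pytest.mark.parametrize("freq", [80, 120, 180, 250, 330, 450])
    def test_pure_tone_recovery_across_range(self, freq):
        track = estimate_pitch(sine(float(freq)), RATE)
        f0 = np.nanmean(track.f0)
        assert abs(f0 - freq) / freq < 0.01

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            estimate_pitch(np.zeros(100), RATE)


class TestPeriods:
    def test_pure_sine_periods(self):
        wave = sine(200.0, duration=0.8)
        track = estimate_pitch(wave, RATE)
        seq = extract_periods(wave, track, RATE)
        T = np.concatenate(seq.periods())
        assert len(T) > 100
        np.testing.assert_allclose(T, 5e-3, rtol=0.01)

    def test_alternating_amplitude_modulation(self):
        # 10% alternating AM at the cycle rate: amplitudes alternate by ~1.1
        t = np.arange(int(0.8 * RATE)) / RATE
        f0 = 200.0
        am = 1.0 + 0.05 * np.sign(np.sin(np.pi * f0 * t + 1e-9))
        wave = am * np.sin(2 * np.pi * f0 * t)
        track = estimate_pitch(wave, RATE)
        seq = extract_periods(wave, track, RATE)
        A = np.concatenate(seq.amplitudes())
        ratio = A[1:] / A[:-1]
        med_hi = np.median(ratio[ratio > 1])
        assert med_hi == pytest.approx(1.1, rel=0.03)

    def test_unvoiced_input_empty(self):
        rng = np.random.default_rng(1)
        wave = 0.1 * rng.standard_normal(RATE // 2)
        track = estimate_pitch(wave, RATE)
        seq = extract_periods(wave, track, RATE)
        assert seq.n_periods == 0


class TestJitterShimmer:
    def test_constant_periods_zero_jitter(self):
        jit = jitter_measures(np.full(50, 5e-3))
        for key in ("local", "local_abs", "rap", "ppq5", "ddp"):
            assert jit[key] == pytest.approx(0.0, abs=1e-15)

    def test_alternating_periods_hand_value(self):
        T = np.tile([5.0e-3, 5.1e-3], 25)
        jit = jitter_measures(T)
        assert jit["local"] == pytest.approx(0.1 / 5.05, rel=1e-3)
        assert jit["local_abs"] == pytest.approx(0.1e-3, rel=1e-3)

    def test_ddp_is_three_rap(self):
        rng = np.random.default_rng(2)
        T = 5e-3 * (1 + 0.02 * rng.standard_normal(40))
        jit = jitter_measures(T)
        assert jit["ddp"] == pytest.approx(3 * jit["rap"], rel=1e-12)

    def test_too_few_periods_missing(self):
        assert np.isnan(jitter_measures([5e-3, 5e-3])["local"])

    def test_time_scaling_invariance(self):
        rng = np.random.default_rng(3)
        T = 5e-3 * (1 + 0.02 * rng.standard_normal(40))
        a, b = jitter_measures(T), jitter_measures(2 * T)
        for key in ("local", "rap", "ppq5", "ddp"):
            assert b[key] == pytest.approx(a[key], rel=1e-12)
        assert b["local_abs"] == pytest.approx(2 * a["local_abs"], rel=1e-12)

    def test_constant_amplitudes_zero_shimmer(self):
        shim = shimmer_measures(np.full(50, 0.7))
        for key in ("local", "local_db", "apq3", "apq5", "apq11", "dda"):
            assert shim[key] == pytest.approx(0.0, abs=1e-12)

    def test_alternating_amplitudes_hand_value(self):
        A = np.tile([1.0, 1.1], 25)
        shim = shimmer_measures(A)
        assert shim["local"] == pytest.approx(0.1 / 1.05, rel=1e-3)

    def test_dda_is_three_apq3(self):
        rng = np.random.default_rng(4)
        A = 1 + 0.1 * rng.random(40)
        shim = shimmer_measures(A)
        assert shim["dda"] == pytest.approx(3 * shim["apq3"], rel=1e-12)

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(5)
        A = 1 + 0.1 * rng.random(40)
        a, b = shimmer_measures(A), shimmer_measures(5 * A)
        for key in ("local", "local_db", "apq3", "apq5", "apq11", "dda"):
            assert b[key] == pytest.approx(a[key], rel=1e-12)

    def test_apq11_needs_eleven(self):
        assert np.isnan(shimmer_measures(1 + 0.01 * np.arange(8))["apq11"])

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValueError):
            shimmer_measures([1.0, -0.5, 1.0])


class TestHNR:
    @staticmethod
    def track_with_r(r_values):
        n = len(r_values)
        return PitchTrack(
            time=np.arange(n) * 0.01,
            f0=np.full(n, 150.0),
            harmonicity_r=np.asarray(r_values, float),
            frame=0.04,
            hop=0.01,
        )

    def test_equal_power_is_zero_db(self):
        assert hnr(self.track_with_r([0.5] * 10))["mean"] == pytest.approx(0.0)

    def test_ten_to_one_power_is_ten_db(self):
        r = 10 / 11
        assert hnr(self.track_with_r([r] * 10))["mean"] == pytest.approx(10.0)

    def test_noiseless_signal_clips_at_40db(self):
        track = estimate_pitch(sine(200.0), RATE)
        out = hnr(track)
        assert out["median"] == pytest.approx(40.0)

    def test_monotone_in_noise_power(self):
        rng = np.random.default_rng(6)
        base = sine(180.0, duration=0.8)
        means = []
        for noise_frac in (0.01, 0.1, 0.5):
            wave = base + noise_frac * rng.standard_normal(len(base))
            means.append(hnr(estimate_pitch(wave, RATE))["mean"])
        assert means[0] > means[1] > means[2]


class TestMFCC:
    def test_zero_signal_finite_and_constant(self):
        out = mfcc_frames(np.zeros(RATE // 2), RATE)
        assert np.all(np.isfinite(out))
        assert np.allclose(out.std(axis=0), 0.0)

    def test_scaling_affects_only_coefficient_zero(self):
        rng = np.random.default_rng(7)
        wave = rng.standard_normal(RATE // 2)
        a = mfcc_mean(wave, RATE)
        b = mfcc_mean(2 * wave, RATE)
        assert abs(b[0] - a[0]) > 1e-3  # additive shift on c0
        assert np.max(np.abs((b - a)[1:])) < 1e-6

    def test_dct_orthonormal_round_trip(self):
        rng = np.random.default_rng(8)
        wave = rng.standard_normal(RATE // 2)
        logE = mel_log_energies(wave, RATE, n_mel=64)
        coeffs = mfcc_frames(wave, RATE, n_coeff=64, n_mel=64)
        back = idct(coeffs, type=2, norm="ortho", axis=1)
        np.testing.assert_allclose(back, logE, atol=1e-6)

    def test_too_many_coefficients_rejected(self):
        with pytest.raises(ValueError):
            mfcc_mean(np.zeros(RATE // 2), RATE, n_coeff=65, n_mel=64)


class TestVoiceSummary:
    def test_sine_rms_energy_closed_form(self):
        vf = voice_summary(sine(200.0, amp=0.6), RATE)
        assert vf.rms_energy == pytest.approx(0.6 / np.sqrt(2), rel=1e-3)

    def test_clean_vowel_recovery(self):
        from sitpipe.simulate import synthesize_voice

        wave = synthesize_voice(200.0, 0.0, 0.0, 40.0, 2.0, RATE, seed=0)
        vf = voice_summary(wave, RATE)
        assert vf.f0_mean == pytest.approx(200.0, abs=1.0)
        assert vf.jitter_local < 0.005
        assert vf.shimmer_local < 0.005
        assert len(vf.mfcc_mean) == 40

    def test_series_has_57_values(self):
        vf = voice_summary(sine(150.0), RATE)
        assert len(vf.as_series()) == 57
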