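import numpy as np
import pytest
from hypothesis import given, strategies as st

from adspeech.audio_io import AudioSignal
from adspeech.errors import InputError
from adspeech.esa import (
    ESA_FIELDS,
    esa_vector,
    estimate_pitch,
    harmonicity,
    hnr_from_autocorr,
    jitter_local,
    measure_jitter_shimmer,
    shimmer_local,
)

from helpers import SR, pulse_train_vowel


class TestPerturbationMeasures:
    @pytest.mark.parametrize("periods,expected", [
        ([10.0, 10.0, 10.0], 0.0),
        ([10.0, 10.2, 9.8, 10.1, 9.9], 2.75),
        ([9.9, 10.1, 9.9, 10.1, 9.9, 10.1], 2.0),
    ])
    def test_jitter_hand_cases(self, periods, expected):
        assert jitter_local(periods) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("amps,expected", [
        ([0.7, 0.7, 0.7, 0.7], 0.0),
        ([1.0, 1.1, 0.9, 1.0], 100 * (0.1 + 0.2 + 0.1) / 3),
    ])
    def test_shimmer_hand_cases(self, amps, expected):
        assert shimmer_local(amps) == pytest.approx(expected, abs=1e-9)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(InputError):
            jitter_local([0.01])
        with pytest.raises(InputError):
            shimmer_local([1.0])

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, a):
        periods = np.array([10.0, 10.3, 9.9, 10.2, 9.8])
        assert jitter_local(a * periods) == pytest.approx(jitter_local(periods), abs=1e-9)
        assert shimmer_local(a * periods) == pytest.approx(shimmer_local(periods), abs=1e-9)


class TestPitch:
    def test_pulse_train_vowel_tracks_f0(self):
        sig = AudioSignal(pulse_train_vowel(1.0, f0=120), SR)
        c = estimate_pitch(sig)
        assert np.nanmedian(c.f0_hz) == pytest.approx(120.0, abs=2.0)

    def test_white_noise_is_mostly_unvoiced(self, rng):
        sig = AudioSignal(rng.normal(0, 0.3, 2 * SR).clip(-1, 1), SR)
        c = estimate_pitch(sig)
        assert (1.0 - c.voiced_mask.mean()) >= 0.90

    def test_linear_ramp_spans_its_range(self):
        t = np.arange(2 * SR) / SR
        f = 100 + 50 * t  # instantaneous frequency 100 -> 200 Hz
        phase = 2 * np.pi * np.cumsum(f) / SR
        x = np.sin(phase) + 0.3 * np.sin(2 * phase)
        c = estimate_pitch(AudioSignal(x / np.max(np.abs(x)), SR))
        assert np.nanmin(c.f0_hz) == pytest.approx(100.0, abs=5.0)
        assert np.nanmax(c.f0_hz) == pytest.approx(200.0, abs=5.0)

    def test_contour_respects_band_and_time_ordering(self):
        sig = AudioSignal(pulse_train_vowel(1.0, f0=150), SR)
        c = estimate_pitch(sig)
        f0 = c.voiced_f0
        assert np.all((f0 >= 50.0) & (f0 <= 500.0))
        assert np.all(np.diff(c.times_s) > 0)


class TestHarmonicity:
    def test_half_correlation_is_zero_db(self):
        assert hnr_from_autocorr(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_clamped_to_range(self):
        assert hnr_from_autocorr(1.0) == 40.0
        assert hnr_from_autocorr(1e-9) == -20.0

    def test_clean_vowel_has_high_hnr(self):
        sig = AudioSignal(pulse_train_vowel(1.5, f0=130), SR)
        hnr, nhr, ac = harmonicity(sig, estimate_pitch(sig))
        assert hnr >= 30.0
        assert ac > 0.9

    def test_known_harmonic_to_noise_ratio_recovered(self, rng):
        t = np.arange(2 * SR) / SR
        harm = sum(np.sin(2 * np.pi * 130 * k * t) / k for k in range(1, 6))
        harm /= np.sqrt(np.mean(harm ** 2))
        noise = rng.standard_normal(len(t))
        noise /= np.sqrt(np.mean(noise ** 2))
        x = harm + noise / np.sqrt(10.0)  # 10 dB harmonic-to-noise energy ratio
        x = x / np.max(np.abs(x))
        sig = AudioSignal(x, SR)
        hnr, _, _ = harmonicity(sig, estimate_pitch(sig))
        assert hnr == pytest.approx(10.0, abs=2.0)

    def test_hnr_decreases_with_noise_level(self, rng):
        base = pulse_train_vowel(1.5, f0=130)
        hnrs = []
        for level in (0.005, 0.02, 0.08):
            x = np.clip(base + rng.normal(0, level, len(base)), -1, 1)
            sig = AudioSignal(x, SR)
            hnrs.append(harmonicity(sig, estimate_pitch(sig))[0])
        assert hnrs[0] > hnrs[1] > hnrs[2]


class TestESAVector:
    def test_fully_voiced_vowel(self):
        sig = AudioSignal(pulse_train_vowel(2.0, f0=140), SR)
        v = esa_vector(sig, estimate_pitch(sig))
        assert v.frac_unvoiced <= 5.0
        assert len(v) == 18 and len(v.to_row()) == 18
        assert v.pitch_min <= v.pitch_mean <= v.pitch_max

    def test_period_stats_consistent_with_contour(self):
        sig = AudioSignal(pulse_train_vowel(2.0, f0=140), SR)
        c = estimate_pitch(sig)
        v = esa_vector(sig, c)
        assert abs(v.period_mean_s - np.mean(1.0 / c.voiced_f0)) < 1e-6

    def test_inserted_silences_raise_voice_break_degree(self):
        vowel = pulse_train_vowel(2.0, f0=140)
        gap = np.zeros(int(0.1 * SR))
        parts, step = [], len(vowel) // 4
        for i in range(4):
            parts.append(vowel[i * step:(i + 1) * step])
            if i < 3:
                parts.append(gap)
        broken = np.concatenate(parts)
        v_broken = esa_vector(AudioSignal(broken, SR), estimate_pitch(AudioSignal(broken, SR)))
        v_clean = esa_vector(AudioSignal(vowel, SR), estimate_pitch(AudioSignal(vowel, SR)))
        assert v_broken.voice_breaks_degree > 0.0
        assert v_broken.voice_breaks_degree > v_clean.voice_breaks_degree

    def test_programmed_perturbations_recovered_on_one_segment(self):
        from adspeech.audio_io import denoise
        from adspeech.synth import DEFAULT_BLOCKS, generate_segment
        sig, truth = generate_segment(DEFAULT_BLOCKS["IS"], 30.0, SR, seed=11)
        s = denoise(sig)
        jit, shim = measure_jitter_shimmer(s, estimate_pitch(s))
        assert jit == pytest.approx(truth.jitter_pct, rel=0.30)
        assert shim == pytest.approx(truth.shimmer_pct, rel=0.30)

    def test_rms_amplitude_scales_linearly(self):
        sig = AudioSignal(pulse_train_vowel(1.0), SR)
        v1 = esa_vector(sig, estimate_pitch(sig))
        half = sig.scaled(0.5)
        v2 = esa_vector(half, estimate_pitch(half))
        assert v2.rms_amplitude == pytest.approx(0.5 * v1.rms_amplitude, rel=1e-6)
        # jitter/shimmer are relative measures: unchanged by amplitude scaling
        assert v2.jitter_local == pytest.approx(v1.jitter_local, abs=0.05)
        assert v2.shimmer_local == pytest.approx(v1.shimmer_local, abs=0.2)

    def test_field_names_are_stable(self):
        sig = AudioSignal(pulse_train_vowel(1.0), SR)
        row = esa_vector(sig, estimate_pitch(sig)).to_row()
        assert list(row) == [f"esa.{f}" for f in ESA_FIELDS]
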