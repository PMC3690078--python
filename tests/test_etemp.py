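import numpy as np
import pytest
from hypothesis import given, strategies as st

from adspeech.audio_io import AudioSignal
from adspeech.errors import InputError
from adspeech.etemp import (
    EmotionalTemperatureModel,
    classify_frames,
    emotional_temperature,
    frame_features,
    normalize_et,
    train_et_model,
)

from helpers import SR, pulse_train_vowel


def gaussian_frames(rng, n_per_class, sep=6.0, n_seg=8):
    """Two Gaussian frame classes, ``sep`` standard deviations apart,
    grouped into segments for p0 calibration."""
    mu = np.zeros(6)
    X0 = rng.normal(mu, 1.0, size=(n_per_class, 6))
    X1 = rng.normal(mu + sep / np.sqrt(6), 1.0, size=(n_per_class, 6))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    per_seg = (2 * n_per_class) // n_seg
    ids = np.repeat(np.arange(n_seg), per_seg)
    n = min(len(X), len(ids))
    return X[:n], y[:n], ids[:n]


class TestFrameFeatures:
    def test_constant_pitch_frame(self):
        sig = AudioSignal(pulse_train_vowel(1.0, f0=150), SR)
        ff = frame_features(sig)
        valid = ff.X[ff.valid]
        assert np.all(np.abs(valid[:, 0]) <= 10.0)          # slope ~ 0 Hz/s
        assert np.median(valid[:, 1]) == pytest.approx(150.0, abs=2.0)

    def test_linear_ramp_slope(self):
        # 100 -> 110 Hz over 0.5 s => slope 20 Hz/s
        sig = AudioSignal(pulse_train_vowel(1.0, f0=100, f0_end=120), SR)
        ff = frame_features(sig)
        slopes = ff.X[ff.valid][:, 0]
        assert np.median(slopes) == pytest.approx(20.0, abs=2.0)

    def test_pure_tone_band_percentages(self):
        t = np.arange(SR) / SR
        sig = AudioSignal(0.5 * np.sin(2 * np.pi * 1000 * t), SR)
        ff = frame_features(sig)
        band = ff.X[:, 2:]
        assert np.allclose(band[:, 1], 100.0, atol=1.0)
        assert np.allclose(band[:, [0, 2, 3]], 0.0, atol=1.0)

    def test_band_percentages_sum_to_100(self, rng):
        sig = AudioSignal(rng.normal(0, 0.2, 3 * SR).clip(-1, 1), SR)
        ff = frame_features(sig)
        sums = ff.X[:, 2:].sum(axis=1)
        assert np.allclose(sums[ff.valid], 100.0, atol=1e-6)

    def test_descriptor_has_two_plus_four_components(self):
        sig = AudioSignal(pulse_train_vowel(1.0), SR)
        assert frame_features(sig).X.shape[1] == 6


class TestNormalizeET:
    def test_threshold_maps_to_50(self):
        for p0 in (10.0, 45.57, 50.0, 80.0):
            assert normalize_et(p0, p0) == pytest.approx(50.0, abs=1e-12)

    def test_endpoints_fixed(self):
        assert normalize_et(0.0, 30.0) == 0.0
        assert normalize_et(100.0, 30.0) == 100.0

    def test_worked_example(self):
        assert normalize_et(90.0, 80.0) == pytest.approx(75.0, abs=1e-12)

    def test_invalid_p0_rejected(self):
        for p0 in (0.0, 100.0, -5.0):
            with pytest.raises(InputError):
                normalize_et(50.0, p0)

    @given(
        st.floats(min_value=0.0, max_value=100.0),
        st.floats(min_value=0.0, max_value=100.0),
        st.floats(min_value=1.0, max_value=99.0),
    )
    def test_monotone_and_bounded(self, r1, r2, p0):
        e1, e2 = normalize_et(r1, p0), normalize_et(r2, p0)
        assert 0.0 <= e1 <= 100.0
        if r1 <= r2:
            assert e1 <= e2 + 1e-12


class TestModel:
    def test_separable_classes_classified_accurately(self, rng):
        X, y, ids = gaussian_frames(rng, 400)
        holdout = rng.random(len(X)) < 0.25
        model = train_et_model(X[~holdout], y[~holdout], ids[~holdout], seed=0)
        acc = np.mean(model.predict(X[holdout]) == y[holdout])
        assert acc >= 0.95

    def test_identical_distributions_are_chance_level(self, rng):
        X = rng.normal(0, 1, size=(800, 6))
        y = np.concatenate([np.zeros(400, int), np.ones(400, int)])
        holdout = rng.random(len(X)) < 0.25
        model = train_et_model(X[~holdout], y[~holdout], seed=0)
        acc = np.mean(model.predict(X[holdout]) == y[holdout])
        assert 0.40 <= acc <= 0.60

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, size=(50, 6))
        with pytest.raises(InputError):
            train_et_model(X, np.ones(50, int), seed=0)

    def test_balanced_input_not_rebalanced(self, rng):
        X, y, ids = gaussian_frames(rng, 100)
        model = EmotionalTemperatureModel(random_state=0)
        Xb, yb, _ = model._rebalance(X, y, ids)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_p0_in_open_interval_and_deterministic(self, rng):
        X, y, ids = gaussian_frames(rng, 200, sep=3.0)
        m1 = train_et_model(X, y, ids, seed=0)
        m2 = train_et_model(X, y, ids, seed=0)
        assert 0.0 < m1.p0_ < 100.0
        assert m1.p0_ == m2.p0_

    def test_save_load_roundtrip(self, rng, tmp_path):
        X, y, ids = gaussian_frames(rng, 150, sep=3.0)
        model = train_et_model(X, y, ids, seed=0)
        model.save(tmp_path / "et.json")
        back = EmotionalTemperatureModel.load(tmp_path / "et.json")
        Xt = rng.normal(0, 2, size=(64, 6))
        assert np.array_equal(model.predict(Xt), back.predict(Xt))
        assert back.p0_ == model.p0_

    def test_classify_frames_at_threshold_is_50(self, rng):
        X, y, ids = gaussian_frames(rng, 200, sep=3.0)
        model = train_et_model(X, y, ids, seed=0)
        pred = model.predict(X)
        # assemble a frame set whose classified percentage equals p0 exactly
        from fractions import Fraction
        frac = Fraction(model.p0_ / 100).limit_denominator(1000)
        n_np, n_tot = frac.numerator, frac.denominator
        np_pool = X[pred == 1]
        pa_pool = X[pred == 0]
        Xe = np.vstack([np_pool[:n_np], pa_pool[: n_tot - n_np]])
        res = classify_frames(Xe, model)
        assert res.raw_pct == pytest.approx(model.p0_, abs=1e-9)
        assert res.et == pytest.approx(50.0, abs=1e-9)


class TestEmotionalTemperature:
    @pytest.fixture(scope="class")
    def small_model(self):
        from adspeech import pipeline
        from adspeech.synth import DEFAULT_BLOCKS, generate_segment
        segs = []
        for lab in ("CR", "AS"):
            for i in range(3):
                s, _ = generate_segment(DEFAULT_BLOCKS[lab], 12.0, SR, seed=i + (0 if lab == "CR" else 40))
                segs.append((f"{lab}{i}", lab, s))
        X, y, ids = pipeline.extract_frame_training_set(segs)
        return train_et_model(X, y, ids, seed=0), segs

    def test_control_scores_above_50_impaired_below(self, small_model):
        model, segs = small_model
        ets = {sid: emotional_temperature(sig, model).et for sid, _, sig in segs}
        assert min(ets[s] for s in ets if s.startswith("CR")) > 50.0
        assert max(ets[s] for s in ets if s.startswith("AS")) < 50.0

    def test_amplitude_invariance(self, small_model):
        model, segs = small_model
        _, _, sig = segs[0]
        e1 = emotional_temperature(sig, model).et
        e2 = emotional_temperature(sig.scaled(0.3), model).et
        assert abs(e1 - e2) <= 1.0

    def test_deterministic(self, small_model):
        model, segs = small_model
        _, _, sig = segs[0]
        r1 = emotional_temperature(sig, model)
        r2 = emotional_temperature(sig, model)
        assert r1.raw_pct == r2.raw_pct and r1.et == r2.et

    def test_all_nonpathological_gives_100(self, small_model):
        from adspeech.etemp import frame_features
        model, segs = small_model
        _, _, sig = segs[0]  # a control segment
        ff = frame_features(sig)
        X = ff.X[ff.valid]
        Xe = X[model.predict(X) == 1]
        assert len(Xe) > 0
        res = classify_frames(Xe, model)
        assert res.raw_pct == 100.0 and res.et == 100.0

    def test_empty_frame_set_yields_missing_result(self, small_model):
        model, _ = small_model
        res = classify_frames(np.empty((0, 6)), model)
        assert np.isnan(res.raw_pct) and np.isnan(res.et)
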