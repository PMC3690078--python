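"""Emotional Temperature: a segment-level pathology score from frame-level SVM votes.

Each half-second frame is described by 6 numbers: 2 prosodic (slope and
intercept of a least-squares line through the frame's voiced pitch
samples) and 4 paralinguistic (percentages of spectral energy in the
bands 0-400, 400-2000, 2000-5000 and 5000-8000 Hz).  An RBF-kernel
support vector machine, trained on a balanced set of frames from control
("non-pathological") and impaired ("pathological") segments, classifies
every frame of a new segment; the raw score is the percentage of frames
voted non-pathological.  The raw percentage is mapped through a piecewise-
linear normalization anchored so that the training decision threshold p0
lands exactly at ET = 50: values above 50 read "control-like", below 50
"pathology-like", on a clinician-friendly 0-100 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import get_window
from sklearn.base import BaseEstimator
from sklearn.svm import SVC

from ._frames import frame_signal, frame_times
from .audio_io import AudioSignal
from .errors import InputError
from .esa import PitchContour, estimate_pitch

DEFAULT_BANDS = ((0.0, 400.0), (400.0, 2000.0), (2000.0, 5000.0), (5000.0, 8000.0))
NON_PATHOLOGICAL, PATHOLOGICAL = 1, 0
N_FRAME_FEATURES = 6  # 2 prosodic + 4 paralinguistic


@dataclass
class FrameFeatures:
    """Per-frame ET descriptors for one segment.

    ``X`` is (n_frames, 6): [pitch_slope Hz/s, pitch_intercept Hz,
    band_pct_0..3].  ``valid`` marks frames usable for classification
    (at least one voiced pitch sample and nonzero spectral energy).
    """

    X: np.ndarray
    valid: np.ndarray
    times_s: np.ndarray


@dataclass
class ETResult:
    """Raw non-pathological frame percentage and normalized Emotional Temperature."""

    raw_pct: float
    et: float


def frame_features(
    signal: AudioSignal,
    contour: PitchContour | None = None,
    frame_length_s: float = 0.5,
    hop_s: float = 0.25,
    bands_hz=DEFAULT_BANDS,
) -> FrameFeatures:
    """Compute the 6-dimensional ET descriptor for every temporal frame.

    The pitch line is fit to the contour's voiced samples inside the frame
    (time measured from the frame start, so the intercept is in Hz at the
    frame onset).  Frames with fewer than 3 voiced samples get slope 0 and
    the frame's median f0 as intercept; frames with no voiced sample or no
    spectral energy are marked invalid and excluded from classification.
    """
    sr = signal.sample_rate
    flen = int(round(frame_length_s * sr))
    hop = int(round(hop_s * sr))
    frames = frame_signal(signal.samples, flen, hop)
    nf = frames.shape[0]
    if nf == 0:
        raise InputError("signal shorter than one ET frame")
    if contour is None:
        contour = estimate_pitch(signal)

    win = get_window("hann", flen)
    power = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    freqs = np.fft.rfftfreq(flen, d=1.0 / sr)
    nyq = sr / 2.0
    band_e = np.stack(
        [power[:, (freqs >= max(0.0, lo)) & (freqs < min(hi, nyq) + 1e-9)].sum(axis=1) for lo, hi in bands_hz],
        axis=1,
    )
    tot = band_e.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        band_pct = 100.0 * band_e / tot[:, None]

    times = frame_times(nf, hop_s, frame_length_s, center=False)
    X = np.zeros((nf, N_FRAME_FEATURES))
    valid = np.ones(nf, dtype=bool)
    for i, t0 in enumerate(times):
        in_frame = (contour.times_s >= t0) & (contour.times_s < t0 + frame_length_s)
        f0 = contour.f0_hz[in_frame]
        tt = contour.times_s[in_frame] - t0
        voiced = np.isfinite(f0)
        if voiced.sum() >= 3:
            slope, intercept = np.polyfit(tt[voiced], f0[voiced], 1)
        elif voiced.sum() >= 1:
            slope, intercept = 0.0, float(np.median(f0[voiced]))
        else:
            slope, intercept = 0.0, 0.0
            valid[i] = False
        X[i, 0], X[i, 1] = slope, intercept
    valid &= tot > 1e-30
    X[:, 2:] = np.where(np.isfinite(band_pct), band_pct, 0.0)
    return FrameFeatures(X=X, valid=valid, times_s=times)


def normalize_et(raw_pct: float, p0: float) -> float:
    """Map the raw non-pathological percentage to the 0-100 ET scale.

    Piecewise-linear, continuous and non-decreasing, fixing 0 -> 0,
    p0 -> 50 and 100 -> 100.
    """
    if not (0.0 < p0 < 100.0):
        raise InputError(f"p0 must lie strictly inside (0, 100), got {p0}")
    if not (0.0 <= raw_pct <= 100.0):
        raise InputError(f"raw_pct must lie in [0, 100], got {raw_pct}")
    if raw_pct <= p0:
        return 50.0 * raw_pct / p0
    return 50.0 + 50.0 * (raw_pct - p0) / (100.0 - p0)


class EmotionalTemperatureModel(BaseEstimator):
    """RBF-SVM frame classifier plus the raw-percentage threshold p0.

    sklearn-style estimator: hyperparameters are constructor arguments,
    fitted state lives in trailing-underscore attributes.  Frame labels are
    1 = non-pathological (control) and 0 = pathological.  ``fit`` expects a
    frame feature matrix, frame labels and, to calibrate p0, the id of the
    segment each frame came from: p0 is the raw-percentage cut that
    maximizes balanced accuracy of separating training segments.

    Parameters
    ----------
    C, gamma : SVC hyperparameters; ``gamma=None`` means 1/n_features on
        the standardized features.
    balance_tol : maximum tolerated class imbalance before the majority
        class is down-sampled (fraction of the larger class).
    random_state : seed for the rebalancing subsample.
    frame_length_s, hop_s, bands_hz : framing used by
        :func:`emotional_temperature` when scoring raw audio.
    """

    def __init__(self, C: float = 1.0, gamma: float | None = None,
                 balance_tol: float = 0.10, random_state: int | None = None,
                 frame_length_s: float = 0.5, hop_s: float = 0.25,
                 bands_hz=DEFAULT_BANDS):
        self.C = C
        self.gamma = gamma
        self.balance_tol = balance_tol
        self.random_state = random_state
        self.frame_length_s = frame_length_s
        self.hop_s = hop_s
        self.bands_hz = bands_hz

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y, segment_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or len(X) != len(y):
            raise InputError("X must be (n_frames, n_features) aligned with y")
        classes = np.unique(y)
        if len(classes) != 2:
            raise InputError(f"need exactly 2 frame classes, got {classes.tolist()}")
        if segment_ids is not None and len(segment_ids) != len(y):
            raise InputError("segment_ids must align with the frame set")

        Xb, yb, ids_b = self._rebalance(X, y, segment_ids)
        self.scaler_mean_ = Xb.mean(axis=0)
        self.scaler_scale_ = Xb.std(axis=0)
        self.scaler_scale_[self.scaler_scale_ == 0] = 1.0
        gamma = self.gamma if self.gamma is not None else 1.0 / X.shape[1]
        svm = SVC(C=self.C, kernel="rbf", gamma=gamma)
        svm.fit(self._standardize(Xb), yb)
        # keep the raw kernel expansion so models round-trip through JSON
        self.gamma_ = float(gamma)
        self.support_vectors_ = svm.support_vectors_.copy()
        self.dual_coef_ = svm.dual_coef_.copy()
        self.intercept_ = float(svm.intercept_[0])
        self.classes_ = svm.classes_.copy()
        self.p0_ = self._calibrate_p0(X, y, segment_ids if segment_ids is not None else None)
        return self

    def _rebalance(self, X, y, segment_ids):
        counts = np.bincount(y, minlength=2)
        n0, n1 = counts[0], counts[1]
        if min(n0, n1) == 0:
            raise InputError("both frame classes must be present")
        if abs(n0 - n1) <= self.balance_tol * max(n0, n1):
            return X, y, segment_ids
        rng = np.random.default_rng(self.random_state)
        minority = int(np.argmin(counts[:2]))
        majority = 1 - minority
        keep_maj = rng.choice(np.flatnonzero(y == majority), size=counts[minority], replace=False)
        idx = np.sort(np.concatenate([np.flatnonzero(y == minority), keep_maj]))
        return X[idx], y[idx], None if segment_ids is None else np.asarray(segment_ids)[idx]

    def _calibrate_p0(self, X, y, segment_ids) -> float:
        """Raw-percentage threshold maximizing balanced segment separation.

        Candidates are the midpoints between consecutive observed
        per-segment raw percentages, restricted to (0, 100); the
        classification rule is: non-pathological if raw >= p0.  Falls back
        to 50 when no usable candidate exists.
        """
        if segment_ids is None:
            return 50.0
        segment_ids = np.asarray(segment_ids)
        pred = self.predict(X)
        raws, labels = [], []
        for sid in np.unique(segment_ids):
            m = segment_ids == sid
            raws.append(100.0 * float(np.mean(pred[m] == NON_PATHOLOGICAL)))
            labels.append(int(np.round(np.mean(y[m]))))
        raws, labels = np.array(raws), np.array(labels)
        uniq = np.unique(raws)
        cands = (uniq[:-1] + uniq[1:]) / 2.0
        cands = cands[(cands > 0.0) & (cands < 100.0)]
        if len(cands) == 0 or len(np.unique(labels)) < 2:
            return 50.0
        best = []
        best_score = -1.0
        for c in cands:
            seg_pred = (raws >= c).astype(int)
            tpr = np.mean(seg_pred[labels == 1] == 1)
            tnr = np.mean(seg_pred[labels == 0] == 0)
            score = 0.5 * (tpr + tnr)
            if score > best_score + 1e-12:
                best, best_score = [c], score
            elif abs(score - best_score) <= 1e-12:
                best.append(c)
        return float(best[len(best) // 2])

    # -- inference ---------------------------------------------------------
    def _standardize(self, X):
        return (np.asarray(X, dtype=float) - self.scaler_mean_) / self.scaler_scale_

    def decision_function(self, X):
        Xs = self._standardize(X)
        d2 = ((Xs[:, None, :] - self.support_vectors_[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-self.gamma_ * d2)
        return K @ self.dual_coef_[0] + self.intercept_

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])

    def raw_percentage(self, X) -> float:
        """Percentage of frames classified non-pathological."""
        pred = self.predict(X)
        return 100.0 * float(np.mean(pred == NON_PATHOLOGICAL))

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Single-file JSON archive: config + standardization + kernel expansion + p0."""
        payload = {
            "format": "adspeech-et-model-v1",
            "params": {
                "C": self.C, "gamma": self.gamma, "balance_tol": self.balance_tol,
                "random_state": self.random_state, "frame_length_s": self.frame_length_s,
                "hop_s": self.hop_s, "bands_hz": [list(b) for b in self.bands_hz],
            },
            "gamma_": self.gamma_,
            "scaler_mean_": self.scaler_mean_.tolist(),
            "scaler_scale_": self.scaler_scale_.tolist(),
            "support_vectors_": self.support_vectors_.tolist(),
            "dual_coef_": self.dual_coef_.tolist(),
            "intercept_": self.intercept_,
            "classes_": self.classes_.tolist(),
            "p0_": self.p0_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "EmotionalTemperatureModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "adspeech-et-model-v1":
            raise InputError(f"not an ET model archive: {path}")
        p = payload["params"]
        p["bands_hz"] = tuple(tuple(b) for b in p["bands_hz"])
        model = cls(**p)
        model.gamma_ = payload["gamma_"]
        model.scaler_mean_ = np.array(payload["scaler_mean_"])
        model.scaler_scale_ = np.array(payload["scaler_scale_"])
        model.support_vectors_ = np.array(payload["support_vectors_"])
        model.dual_coef_ = np.array(payload["dual_coef_"])
        model.intercept_ = payload["intercept_"]
        model.classes_ = np.array(payload["classes_"])
        model.p0_ = payload["p0_"]
        return model


def train_et_model(
    X, y, segment_ids=None, gamma: float | None = None, C: float = 1.0,
    seed: int | None = None, **kwargs,
) -> EmotionalTemperatureModel:
    """Convenience wrapper over :class:`EmotionalTemperatureModel`."""
    return EmotionalTemperatureModel(C=C, gamma=gamma, random_state=seed, **kwargs).fit(
        X, y, segment_ids=segment_ids
    )


def classify_frames(X_valid, model: EmotionalTemperatureModel) -> ETResult:
    """Score an already-extracted set of classifiable frame vectors."""
    X_valid = np.asarray(X_valid, dtype=float)
    if len(X_valid) == 0:
        return ETResult(raw_pct=np.nan, et=np.nan)
    raw = model.raw_percentage(X_valid)
    return ETResult(raw_pct=raw, et=normalize_et(raw, model.p0_))


def emotional_temperature(signal: AudioSignal, model: EmotionalTemperatureModel) -> ETResult:
    """Classify every frame of a segment and normalize the vote percentage.

    Returns NaNs when the segment yields no classifiable frame.
    """
    ff = frame_features(
        signal, frame_length_s=model.frame_length_s, hop_s=model.hop_s, bands_hz=model.bands_hz
    )
    return classify_frames(ff.X[ff.valid], model)
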