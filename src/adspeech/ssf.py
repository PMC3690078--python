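"""Spontaneous Speech Fluency features.

Three families computed per 60-s analysis segment:

* duration — statistics of voiced and unvoiced interval durations from the
  VAD (silence and unvoiced are pooled as "unvoiced": pauses are the signal
  of interest, not their acoustic subtype), a log-spaced duration histogram
  over the most relevant (longest) intervals, the voiced/unvoiced time
  percentage and the slope of the voiced percentage across 10-s windows
  ("speech evolution");
* time domain — short-time energy (mean of squared samples per frame),
  median-filtered;
* frequency domain — spectral centroid ("centre of gravity" of the
  magnitude spectrum), median-filtered.

Duration features depend only on the segmentation and are therefore
invariant to amplitude scaling; short-time energy scales quadratically and
the centroid is scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window, medfilt

from ._frames import frame_signal
from .audio_io import AudioSignal
from .errors import InputError
from .vad import SILENCE, UNVOICED, VOICED, VoicingSegmentation

#: Log-spaced duration histogram support: 10 ms to 10 s.
HIST_MIN_S, HIST_MAX_S = 0.01, 10.0


@dataclass
class SSFFeatureVector:
    voiced_hist: np.ndarray
    unvoiced_hist: np.ndarray
    voiced_mean_s: float
    voiced_max_s: float
    voiced_min_s: float
    voiced_rel_mean_s: float
    unvoiced_mean_s: float
    unvoiced_max_s: float
    unvoiced_min_s: float
    unvoiced_rel_mean_s: float
    voiced_pct: float
    unvoiced_pct: float
    speech_evolution_slope: float
    ste_mean: float
    ste_std: float
    centroid_mean_hz: float
    centroid_std_hz: float

    def to_row(self, prefix: str = "ssf.") -> dict[str, float]:
        """Flatten to named columns in a fixed, documented order."""
        row: dict[str, float] = {}
        for i, v in enumerate(self.voiced_hist):
            row[f"{prefix}voiced_hist_{i}"] = float(v)
        for i, v in enumerate(self.unvoiced_hist):
            row[f"{prefix}unvoiced_hist_{i}"] = float(v)
        for name in (
            "voiced_mean_s", "voiced_max_s", "voiced_min_s", "voiced_rel_mean_s",
            "unvoiced_mean_s", "unvoiced_max_s", "unvoiced_min_s", "unvoiced_rel_mean_s",
            "voiced_pct", "unvoiced_pct", "speech_evolution_slope",
            "ste_mean", "ste_std", "centroid_mean_hz", "centroid_std_hz",
        ):
            row[f"{prefix}{name}"] = float(getattr(self, name))
        return row

    def __len__(self) -> int:
        return len(self.voiced_hist) + len(self.unvoiced_hist) + 15


def _relevant(durations: np.ndarray, quantile: float) -> np.ndarray:
    """The longest ``quantile`` fraction of intervals (at least one)."""
    if len(durations) == 0:
        return durations
    k = max(1, int(np.ceil(quantile * len(durations))))
    return np.sort(durations)[-k:]


def _log_hist(durations: np.ndarray, n_bins: int) -> np.ndarray:
    if len(durations) == 0:
        return np.zeros(n_bins)
    edges = np.logspace(np.log10(HIST_MIN_S), np.log10(HIST_MAX_S), n_bins + 1)
    counts, _ = np.histogram(np.clip(durations, HIST_MIN_S, HIST_MAX_S), bins=edges)
    return counts / counts.sum() if counts.sum() else np.zeros(n_bins)


def duration_features(
    seg: VoicingSegmentation,
    n_bins: int = 10,
    relevance_quantile: float = 0.2,
    evolution_window_s: float = 10.0,
) -> dict[str, object]:
    """Duration family of the fluency features.

    ``unvoiced`` pools the VAD's unvoiced and silence intervals.  The
    histogram is computed over the most relevant (longest
    ``relevance_quantile`` fraction of) intervals per class, on log-spaced
    bins from 10 ms to 10 s.  ``speech_evolution_slope`` is the
    least-squares slope of the per-window voiced percentage against window
    index (window length ``evolution_window_s``), in percentage points per
    window; 0 when fewer than two whole windows fit.
    """
    if seg.duration_s <= 0:
        raise InputError("segmentation covers zero duration")
    voiced = seg.durations(VOICED)
    unvoiced = np.concatenate([seg.durations(UNVOICED), seg.durations(SILENCE)])

    def stats(d: np.ndarray) -> tuple[float, float, float, float]:
        if len(d) == 0:
            return 0.0, 0.0, 0.0, 0.0
        return float(d.mean()), float(d.max()), float(d.min()), float(_relevant(d, relevance_quantile).mean())

    v_mean, v_max, v_min, v_rel = stats(voiced)
    u_mean, u_max, u_min, u_rel = stats(unvoiced)
    total = seg.duration_s
    voiced_pct = 100.0 * voiced.sum() / total if len(voiced) else 0.0

    # voiced percentage per consecutive window, slope against window index
    n_win = int(seg.duration_s // evolution_window_s)
    slope = 0.0
    if n_win >= 2:
        pcts = []
        for w in range(n_win):
            t0, t1 = w * evolution_window_s, (w + 1) * evolution_window_s
            v = sum(
                max(0.0, min(e, t1) - max(s, t0))
                for (s, e, lab) in seg.intervals if lab == VOICED
            )
            pcts.append(100.0 * v / evolution_window_s)
        slope = float(np.polyfit(np.arange(n_win), pcts, 1)[0])

    return {
        "voiced_hist": _log_hist(_relevant(voiced, relevance_quantile), n_bins),
        "unvoiced_hist": _log_hist(_relevant(unvoiced, relevance_quantile), n_bins),
        "voiced_mean_s": v_mean, "voiced_max_s": v_max, "voiced_min_s": v_min,
        "voiced_rel_mean_s": v_rel,
        "unvoiced_mean_s": u_mean, "unvoiced_max_s": u_max, "unvoiced_min_s": u_min,
        "unvoiced_rel_mean_s": u_rel,
        "voiced_pct": voiced_pct, "unvoiced_pct": 100.0 - voiced_pct,
        "speech_evolution_slope": slope,
    }


def short_time_energy(
    signal: AudioSignal,
    frame_length_s: float = 0.025,
    hop_s: float = 0.010,
    median_filter: int = 5,
) -> tuple[np.ndarray, float, float]:
    """Per-frame mean of squared samples, median-filtered.

    Returns (series, mean, std).
    """
    sr = signal.sample_rate
    frames = frame_signal(signal.samples, int(round(frame_length_s * sr)), int(round(hop_s * sr)))
    if frames.shape[0] == 0:
        raise InputError("signal shorter than one frame")
    ste = (frames ** 2).mean(axis=1)
    ste = _median_filter_series(ste, median_filter)
    return ste, float(ste.mean()), float(ste.std())


def _median_filter_series(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1 or len(x) < 3:
        return x
    k = min(k, len(x) if len(x) % 2 == 1 else len(x) - 1)
    if k % 2 == 0:
        k -= 1
    return medfilt(x, kernel_size=k) if k >= 3 else x


def spectral_centroid(
    signal: AudioSignal,
    frame_length_s: float = 0.025,
    hop_s: float = 0.010,
    median_filter: int = 5,
) -> tuple[np.ndarray, float, float]:
    """Per-frame spectral centroid in Hz (Hann window), median-filtered.

    Frames whose total spectral magnitude is below 1e-12 yield NaN and are
    excluded from the returned mean/std.
    """
    sr = signal.sample_rate
    flen = int(round(frame_length_s * sr))
    frames = frame_signal(signal.samples, flen, int(round(hop_s * sr)))
    if frames.shape[0] == 0:
        raise InputError("signal shorter than one frame")
    win = get_window("hann", flen)
    mags = np.abs(np.fft.rfft(frames * win, axis=1))
    freqs = np.fft.rfftfreq(flen, d=1.0 / sr)
    tot = mags.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cent = (mags * freqs).sum(axis=1) / tot
    cent[tot < 1e-12] = np.nan
    valid = cent[np.isfinite(cent)]
    filt = _median_filter_series(np.nan_to_num(cent, nan=0.0), median_filter)
    filt[~np.isfinite(cent)] = np.nan
    if len(valid) == 0:
        return filt, np.nan, np.nan
    return filt, float(np.nanmean(filt)), float(np.nanstd(filt))


def ssf_vector(
    signal: AudioSignal,
    seg: VoicingSegmentation,
    n_bins: int = 10,
    relevance_quantile: float = 0.2,
    evolution_window_s: float = 10.0,
    frame_length_s: float = 0.025,
    hop_s: float = 0.010,
    median_filter: int = 5,
) -> SSFFeatureVector:
    """Concatenate the duration, time-domain and frequency-domain families."""
    dur = duration_features(seg, n_bins, relevance_quantile, evolution_window_s)
    _, ste_mean, ste_std = short_time_energy(signal, frame_length_s, hop_s, median_filter)
    _, c_mean, c_std = spectral_centroid(signal, frame_length_s, hop_s, median_filter)
    return SSFFeatureVector(
        ste_mean=ste_mean, ste_std=ste_std,
        centroid_mean_hz=c_mean, centroid_std_hz=c_std,
        **dur,
    )
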