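"""Audio input/output, denoising and fixed-length segmentation.

The analysis unit throughout the package is a mono waveform at 16 kHz,
cut into consecutive non-overlapping 60-second segments.  Recordings at
other rates or with multiple channels are converted on load.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import ShortTimeFFT, get_window, resample_poly

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 16_000
#: STFT convention reused everywhere short frames are needed: 25 ms Hann, 10 ms hop.
FRAME_LENGTH_S = 0.025
HOP_S = 0.010


@dataclass(frozen=True)
class AudioSignal:
    """Mono waveform with samples in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1:
            raise InputError(f"AudioSignal must be mono 1-D, got shape {s.shape}")
        if not np.all(np.isfinite(s)):
            raise InputError("AudioSignal contains non-finite samples")
        if int(self.sample_rate) <= 0:
            raise InputError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)

    def scaled(self, factor: float) -> "AudioSignal":
        return AudioSignal(self.samples * factor, self.sample_rate)


@dataclass
class SegmentedRecording:
    """Consecutive, non-overlapping fixed-length slices of one recording."""

    segments: list[AudioSignal]
    segment_length_s: float
    source_id: str = ""
    dropped_s: float = 0.0

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def _to_float(data: np.ndarray) -> np.ndarray:
    """Normalize integer PCM by full scale; pass float input through."""
    if data.dtype == np.int16:
        return data.astype(float) / 32768.0
    if data.dtype == np.int32:
        return data.astype(float) / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(float) - 128.0) / 128.0
    return data.astype(float)


def load_wav(path, target_rate: int = DEFAULT_SAMPLE_RATE) -> AudioSignal:
    """Read a RIFF/WAVE file as a mono float signal at ``target_rate``.

    Multi-channel audio is averaged to mono.  Resampling uses a polyphase
    filter (anti-aliased).  If the file's peak exceeds full scale (possible
    for IEEE-float WAV) the signal is rescaled to peak 1.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise InputError(f"cannot read audio file: {path} (not found)")
    except Exception as exc:  # unreadable / malformed
        raise InputError(f"cannot read audio file: {path} ({exc})")
    if data.size == 0:
        raise InputError(f"audio file is empty: {path}")
    x = _to_float(np.asarray(data))
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != target_rate:
        fr = Fraction(int(target_rate), int(rate))
        x = resample_poly(x, fr.numerator, fr.denominator)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 1.0:
        x = x / peak
    return AudioSignal(x, target_rate)


def save_wav(path, signal: AudioSignal) -> None:
    """Write 16-bit PCM WAV."""
    x = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(Path(path), signal.sample_rate, pcm)


def _stft_transform(sr: int, frame_length_s: float = FRAME_LENGTH_S, hop_s: float = HOP_S) -> ShortTimeFFT:
    nperseg = int(round(frame_length_s * sr))
    hop = int(round(hop_s * sr))
    win = get_window("hann", nperseg)
    return ShortTimeFFT(win, hop=hop, fs=sr)


def denoise(
    signal: AudioSignal,
    noise_profile_s: float = 0.25,
    over_subtraction: float = 1.0,
) -> AudioSignal:
    """Stationary-noise removal by magnitude spectral subtraction.

    The noise magnitude spectrum is estimated from the lowest-energy STFT
    frames (totalling ``noise_profile_s`` seconds), scaled by
    ``over_subtraction`` and subtracted from every frame with half-wave
    rectification and a spectral floor of 0.01x the noise magnitude.
    Output length equals input length.
    """
    sr = signal.sample_rate
    nperseg = int(round(FRAME_LENGTH_S * sr))
    if len(signal) < nperseg:
        raise InputError(
            f"signal too short to denoise: {len(signal)} samples < one {nperseg}-sample frame"
        )
    if signal.duration_s <= noise_profile_s:
        raise InputError("signal must be longer than the noise profile duration")
    stf = _stft_transform(sr)
    S = stf.stft(signal.samples)
    mag = np.abs(S)
    frame_energy = (mag ** 2).sum(axis=0)
    n_noise = max(1, int(math.ceil(noise_profile_s / HOP_S)))
    n_noise = min(n_noise, mag.shape[1])
    idx = np.argsort(frame_energy)[:n_noise]
    noise_mag = mag[:, idx].mean(axis=1, keepdims=True)

    out_mag = np.maximum(mag - over_subtraction * noise_mag, 0.01 * noise_mag)
    phase = np.where(mag > 0, S / np.maximum(mag, 1e-30), 1.0)
    y = stf.istft(out_mag * phase, k1=len(signal))
    y = np.asarray(y, dtype=float)[: len(signal)]
    if len(y) < len(signal):
        y = np.pad(y, (0, len(signal) - len(y)))
    return AudioSignal(np.clip(y, -1.0, 1.0), sr)


def segment_fixed(signal: AudioSignal, segment_length_s: float = 60.0, source_id: str = "") -> SegmentedRecording:
    """Cut a recording into consecutive fixed-length segments.

    A trailing remainder shorter than ``segment_length_s`` is dropped and
    logged; a recording shorter than one segment yields an empty (but valid)
    ``SegmentedRecording`` with a warning.
    """
    if segment_length_s <= 0:
        raise InputError(f"segment_length_s must be positive, got {segment_length_s}")
    sps = int(round(segment_length_s * signal.sample_rate))
    n = len(signal) // sps
    segments = [
        AudioSignal(signal.samples[i * sps:(i + 1) * sps], signal.sample_rate) for i in range(n)
    ]
    dropped = (len(signal) - n * sps) / signal.sample_rate
    if n == 0:
        warnings.warn(
            f"recording {source_id or '<unnamed>'} is shorter than one "
            f"{segment_length_s}-s segment; no segments produced", stacklevel=2,
        )
    elif dropped > 0:
        logger.info("dropped %.3f s trailing remainder of %s", dropped, source_id or "<unnamed>")
    return SegmentedRecording(segments, segment_length_s, source_id, dropped)
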