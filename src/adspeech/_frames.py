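"""Short-time framing and normalized autocorrelation primitives.

All frame-based operations in the package use the same convention: frame ``i``
starts at sample ``i * hop`` and spans ``frame_len`` samples; only complete
frames are produced.
"""

from __future__ import annotations

import numpy as np


def n_frames(n_samples: int, frame_len: int, hop: int) -> int:
    if n_samples < frame_len:
        return 0
    return 1 + (n_samples - frame_len) // hop


def frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Slice ``x`` into a (n_frames, frame_len) matrix of complete frames."""
    nf = n_frames(len(x), frame_len, hop)
    if nf == 0:
        return np.empty((0, frame_len), dtype=float)
    view = np.lib.stride_tricks.sliding_window_view(x, frame_len)[::hop]
    return np.ascontiguousarray(view[:nf], dtype=float)


def frame_times(nf: int, hop_s: float, frame_length_s: float, center: bool = False) -> np.ndarray:
    t = np.arange(nf) * hop_s
    if center:
        t = t + frame_length_s / 2.0
    return t


def _normalized_autocorr(frames: np.ndarray) -> np.ndarray:
    """Per-lag energy-normalized autocorrelation matrix (n_frames, N).

    Normalization per lag uses the geometric mean of the energies of the two
    overlapping stretches, so a perfectly periodic frame scores r = 1
    regardless of how many periods it contains.
    """
    F = frames - frames.mean(axis=1, keepdims=True)
    nf, N = F.shape
    nfft = 1 << int(np.ceil(np.log2(2 * N)))
    S = np.fft.rfft(F, nfft)
    C = np.fft.irfft(np.abs(S) ** 2, nfft)[:, :N]
    e = F ** 2
    cum = np.cumsum(e, axis=1)
    tot = cum[:, -1:]
    lags_all = np.arange(N)
    # E1(tau) = energy of x[0 : N-tau], E2(tau) = energy of x[tau : N]
    E1 = cum[:, N - 1 - lags_all]
    E2 = tot - np.concatenate([np.zeros((nf, 1)), cum[:, :-1]], axis=1)
    return C / np.sqrt(E1 * E2 + 1e-30)


def _parabolic(R: np.ndarray, k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sub-sample refinement of per-row peaks at integer lags ``k``."""
    nf, N = R.shape
    rows = np.arange(nf)
    k = np.clip(k, 1, N - 2)
    rm1, r0, rp1 = R[rows, k - 1], R[rows, k], R[rows, k + 1]
    denom = rm1 - 2 * r0 + rp1
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (rm1 - rp1) / np.where(denom == 0, 1, denom), 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    return k + delta, r0 - 0.25 * (rm1 - rp1) * delta


def autocorr_peaks(
    frames: np.ndarray, min_lag: int, max_lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame strongest normalized-autocorrelation peak in a lag band.

    Parameters
    ----------
    frames : (n_frames, N) array, not yet mean-subtracted.
    min_lag, max_lag : inclusive lag band in samples.

    Returns
    -------
    lags : float array, parabolic-refined peak lag per frame (samples).
    peaks : float array in [0, 1], refined normalized autocorrelation.
    """
    F = np.asarray(frames, dtype=float)
    if F.ndim != 2 or F.shape[0] == 0:
        return np.empty(0), np.empty(0)
    nf, N = F.shape
    min_lag = max(1, int(min_lag))
    max_lag = min(int(max_lag), N - 2)
    if max_lag <= min_lag:
        return np.full(nf, np.nan), np.zeros(nf)
    R = _normalized_autocorr(F)
    k = R[:, min_lag:max_lag + 1].argmax(axis=1) + min_lag
    lag, peak = _parabolic(R, k)
    return lag, np.clip(peak, 0.0, 1.0)


def autocorr_candidates(
    frames: np.ndarray, min_lag: int, max_lag: int, n_cand: int = 4, tol: float = 0.85
) -> tuple[np.ndarray, np.ndarray]:
    """Top local-maximum pitch-period candidates per frame.

    Returns (lags, peaks), each (n_frames, n_cand), sorted by descending
    peak value and NaN-padded.  Candidates are local maxima of the
    normalized autocorrelation within the band whose value reaches ``tol``
    times the band maximum — the material for harmonic/subharmonic
    disambiguation by the caller.
    """
    F = np.asarray(frames, dtype=float)
    nf, N = F.shape
    min_lag = max(1, int(min_lag))
    max_lag = min(int(max_lag), N - 2)
    R = _normalized_autocorr(F)
    band = R[:, min_lag:max_lag + 1]
    rmax = band.max(axis=1)
    left = np.concatenate([np.full((nf, 1), -np.inf), band[:, :-1]], axis=1)
    right = np.concatenate([band[:, 1:], np.full((nf, 1), -np.inf)], axis=1)
    is_max = (band > left) & (band >= right) & (band >= tol * rmax[:, None])
    # always keep the global argmax even on a band edge
    is_max[np.arange(nf), band.argmax(axis=1)] = True

    lags_out = np.full((nf, n_cand), np.nan)
    peaks_out = np.full((nf, n_cand), np.nan)
    masked = np.where(is_max, band, -np.inf)
    order = np.argsort(-masked, axis=1)[:, :n_cand]
    for j in range(n_cand):
        k = order[:, j] + min_lag
        valid = masked[np.arange(nf), order[:, j]] > -np.inf
        lag, peak = _parabolic(R, k)
        lags_out[valid, j] = lag[valid]
        peaks_out[valid, j] = np.clip(peak[valid], 0.0, 1.0)
    return lags_out, peaks_out
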