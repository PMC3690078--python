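"""Higuchi fractal dimension (HFD) of waveforms.

Higuchi's estimator measures the fractal dimension of a discrete time
series directly: for each scale k the mean normalized curve length L(k) of
k interleaved subsampled versions of the series is computed, and the
dimension is the slope of ln L(k) against ln(1/k).  Smooth curves give
HFD -> 1, uncorrelated noise gives HFD -> 2, and fractional Brownian
motion with Hurst exponent H gives HFD = 2 - H.

The HFD is computed on sliding waveform windows; FD1 is the mean of the
per-window HFD series, FD2 adds its max, min, variance and standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._frames import frame_signal
from .audio_io import AudioSignal
from .errors import DegenerateInputError, InputError


@dataclass
class FDFeatureVector:
    """Statistics of the per-window HFD series; ``fd_mean`` is the FD1 feature."""

    fd_mean: float
    fd_max: float
    fd_min: float
    fd_var: float
    fd_std: float

    def to_row(self, prefix: str = "fd.") -> dict[str, float]:
        return {
            f"{prefix}mean": self.fd_mean,
            f"{prefix}max": self.fd_max,
            f"{prefix}min": self.fd_min,
            f"{prefix}var": self.fd_var,
            f"{prefix}std": self.fd_std,
        }


def higuchi_fd(series, kmax: int = 8) -> float:
    """Higuchi fractal dimension of a 1-D series.

    For k = 1..kmax and offsets m = 1..k the curve length is

        L_m(k) = (N-1) / (floor((N-m)/k) * k^2) * sum_i |x(m+ik) - x(m+(i-1)k)|

    L(k) is the mean over m, and the HFD is the least-squares slope of
    ln L(k) against ln(1/k).

    Raises
    ------
    InputError
        if the series is shorter than 10*kmax samples.
    DegenerateInputError
        if the series is constant (curve length is zero at every scale).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InputError("series must be 1-D")
    N = len(x)
    if kmax < 2:
        raise InputError(f"kmax must be >= 2, got {kmax}")
    if N < 10 * kmax:
        raise InputError(f"series too short for HFD: N={N} < 10*kmax={10 * kmax}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has no defined fractal dimension")

    ks = np.arange(1, kmax + 1)
    L = np.empty(kmax)
    for k in ks:
        lengths = []
        for m in range(1, k + 1):
            sub = x[m - 1::k]
            n_i = len(sub) - 1
            if n_i < 1:
                continue
            lengths.append((N - 1) / (n_i * k * k) * np.abs(np.diff(sub)).sum())
        L[k - 1] = np.mean(lengths)
    slope = np.polyfit(np.log(1.0 / ks), np.log(L), 1)[0]
    return float(slope)


def higuchi_fd_windows(windows: np.ndarray, kmax: int = 8) -> np.ndarray:
    """Vectorized HFD over the rows of a (n_windows, N) matrix.

    Constant rows yield NaN (skipped by callers).  Matches ``higuchi_fd``
    row-wise to floating-point rounding.
    """
    W = np.asarray(windows, dtype=float)
    nw, N = W.shape
    ks = np.arange(1, kmax + 1)
    L = np.empty((nw, kmax))
    for k in ks:
        acc = np.zeros(nw)
        cnt = 0
        for m in range(1, k + 1):
            sub = W[:, m - 1::k]
            n_i = sub.shape[1] - 1
            if n_i < 1:
                continue
            acc += (N - 1) / (n_i * k * k) * np.abs(np.diff(sub, axis=1)).sum(axis=1)
            cnt += 1
        L[:, k - 1] = acc / cnt
    const = np.ptp(W, axis=1) == 0
    with np.errstate(divide="ignore"):
        logL = np.log(L)
    logL[const] = 0.0  # placeholder; rows are overwritten with NaN below
    X = np.vstack([np.log(1.0 / ks), np.ones(kmax)]).T
    coef, *_ = np.linalg.lstsq(X, logL.T, rcond=None)
    fd = coef[0]
    fd[const] = np.nan
    return fd


def fd_features(
    signal: AudioSignal,
    window_s: float = 1.0,
    hop_s: float = 0.5,
    kmax: int = 8,
) -> FDFeatureVector:
    """HFD over sliding windows and its summary statistics.

    Constant (e.g. digitally silent) windows are skipped.  Variance is the
    population variance of the window series; ``fd_std`` is its square root.
    """
    sr = signal.sample_rate
    wlen = int(round(window_s * sr))
    windows = frame_signal(signal.samples, wlen, int(round(hop_s * sr)))
    if windows.shape[0] == 0:
        raise InputError(f"signal shorter than one {window_s}-s window")
    fds = higuchi_fd_windows(windows, kmax)
    fds = fds[np.isfinite(fds)]
    if len(fds) == 0:
        raise InputError("no non-constant window available for HFD")
    var = float(fds.var())
    return FDFeatureVector(
        fd_mean=float(fds.mean()),
        fd_max=float(fds.max()),
        fd_min=float(fds.min()),
        fd_var=var,
        fd_std=float(np.sqrt(var)),
    )
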