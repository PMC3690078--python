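"""Shared synthetic fixtures and independent oracles for the test suite.

Everything here is deliberately simple and separate from the package's own
signal paths, so it can serve as an independent check.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

SR = 16_000


def pulse_train_vowel(
    duration_s: float,
    f0: float = 120.0,
    sr: int = SR,
    formants=((500, 80), (1500, 120), (2500, 160)),
    amp: float = 0.5,
    f0_end: float | None = None,
) -> np.ndarray:
    """Synthetic vowel: impulse train through formant resonators.

    ``f0_end`` makes the fundamental ramp linearly from ``f0`` to it.
    Independent of the package's generator (no jitter/shimmer machinery).
    """
    n = int(duration_s * sr)
    e = np.zeros(n)
    t, phase = 0.0, 0.0
    while True:
        frac = t / duration_s
        f = f0 if f0_end is None else f0 + (f0_end - f0) * frac
        t += 1.0 / f
        i = int(t * sr)
        if i >= n:
            break
        e[i] = 1.0
    v = e
    for f, bw in formants:
        r = np.exp(-np.pi * bw / sr)
        th = 2 * np.pi * f / sr
        v = lfilter([1 - r], [1, -2 * r * np.cos(th), r * r], v)
    peak = np.max(np.abs(v))
    return v / peak * amp if peak > 0 else v


def fbm_davies_harte(n: int, H: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Brownian motion by circulant spectral synthesis.

    Fractional Gaussian noise is sampled from the spectral (eigenvalue)
    decomposition of its circulant-embedded covariance and cumulated.
    """
    def gamma(k):
        k = np.abs(k)
        return 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))

    r = gamma(np.arange(n))
    row = np.concatenate([r, r[-2:0:-1]])
    lam = np.clip(np.fft.fft(row).real, 0.0, None)
    m = len(row)
    W = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    fgn = np.fft.fft(np.sqrt(lam / (2 * m)) * W).real[:n]
    return np.cumsum(fgn)


def higuchi_naive(x, kmax: int) -> float:
    """Literal, loop-based Higuchi estimator (brute-force oracle)."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    L = []
    for k in range(1, kmax + 1):
        Lm = []
        for m in range(1, k + 1):
            n_i = (N - m) // k
            if n_i < 1:
                continue
            s = 0.0
            for i in range(1, n_i + 1):
                s += abs(x[m + i * k - 1] - x[m + (i - 1) * k - 1])
            Lm.append((N - 1) / (n_i * k * k) * s)
        L.append(sum(Lm) / len(Lm))
    ks = np.arange(1, kmax + 1)
    return float(np.polyfit(np.log(1.0 / ks), np.log(L), 1)[0])
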