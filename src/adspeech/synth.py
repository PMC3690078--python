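"""Synthetic speech cohorts with exact ground truth.

Source-filter synthesis: a glottal pulse train with per-cycle period
perturbation (jitter) and amplitude perturbation (shimmer), an AR(1)
random-walk f0 contour, three formant resonators and a one-pole spectral
tilt filter.  Utterances alternate with pauses drawn from a log-normal
distribution; brief intra-utterance voicing breaks are inserted at a
programmed rate; white noise sets the floor.  Durations are budgeted in
samples so the programmed voiced fraction is met exactly (up to one-sample
rounding of the budget itself), and every quantity the analysis side
estimates (voicing intervals, f0 track, pulse times) is recorded as
generated.

The four class blocks encode the contrasts reported for progressive
dementia severity: shorter utterances, longer and more variable pauses,
lower voiced fraction, flatter pitch, higher jitter/shimmer, more voice
breaks and steeper spectral tilt along control -> early -> intermediate ->
advanced.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .audio_io import AudioSignal, save_wav
from .errors import InputError

CLASSES = ("CR", "ES", "IS", "AS")
#: |diff| of iid Gaussian perturbations has mean 2*sigma/sqrt(pi); dividing the
#: programmed local-perturbation percentage by this factor makes the *expected
#: measured* local jitter/shimmer equal the programmed value.
_LOCAL_FACTOR = 2.0 / np.sqrt(np.pi)


@dataclass(frozen=True)
class ClassBlock:
    """Per-class generator parameters."""

    f0_mean_hz: float
    f0_range_hz: float
    jitter_pct: float
    shimmer_pct: float
    voiced_fraction: float
    pause_mean_s: float
    pause_cv: float
    utterance_mean_s: float
    voice_break_rate_per_min: float
    noise_floor_db: float
    spectral_tilt_db_oct: float

    def validate(self):
        if not (0.0 < self.voiced_fraction < 1.0):
            raise InputError(f"voiced_fraction must be in (0,1), got {self.voiced_fraction}")
        if not (50.0 <= self.f0_mean_hz <= 500.0):
            raise InputError(f"f0_mean_hz out of physical range: {self.f0_mean_hz}")
        for name in ("jitter_pct", "shimmer_pct", "pause_mean_s", "pause_cv",
                     "utterance_mean_s", "voice_break_rate_per_min"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.noise_floor_db >= 0:
            raise InputError("noise_floor_db must be negative (dB below speech RMS)")


#: Default study conditions: a monotone severity gradient along the dimensions
#: dementia affects in spontaneous speech.  Voiced fraction strictly decreases
#: CR > ES > IS > AS.
DEFAULT_BLOCKS: dict[str, ClassBlock] = {
    "CR": ClassBlock(140.0, 60.0, 0.8, 5.0, 0.55, 0.6, 0.6, 3.0, 2.0, -20.0, -6.0),
    "ES": ClassBlock(135.0, 45.0, 1.2, 6.5, 0.45, 0.9, 0.7, 2.2, 4.0, -20.0, -8.0),
    "IS": ClassBlock(130.0, 35.0, 1.8, 8.0, 0.35, 1.3, 0.8, 1.6, 7.0, -20.0, -10.0),
    "AS": ClassBlock(125.0, 25.0, 2.6, 10.0, 0.25, 1.8, 0.9, 1.2, 10.0, -20.0, -12.0),
}

#: Class sizes mirroring the study's balanced subset: 20 controls and 20
#: impaired split 4 early / 10 intermediate / 6 advanced.
DEFAULT_N_SEGMENTS = {"CR": 20, "ES": 4, "IS": 10, "AS": 6}


@dataclass
class CohortSpec:
    blocks: dict[str, ClassBlock] = field(default_factory=lambda: dict(DEFAULT_BLOCKS))
    n_segments: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_SEGMENTS))
    segment_length_s: float = 60.0
    sample_rate: int = 16_000
    seed: int = 0

    def validate(self):
        for name, block in self.blocks.items():
            if name not in CLASSES:
                raise InputError(f"unknown class {name!r}")
            block.validate()
        order = [self.blocks[c].voiced_fraction for c in CLASSES if c in self.blocks]
        if any(a <= b for a, b in zip(order, order[1:])):
            raise InputError("voiced_fraction must strictly decrease CR > ES > IS > AS")


@dataclass
class GroundTruth:
    """Exact annotations recorded while generating one segment."""

    label: str
    voicing_intervals: list[tuple[float, float, str]]  # (start_s, end_s, voiced|unvoiced)
    f0_times_s: np.ndarray
    f0_hz: np.ndarray
    pulse_times_s: np.ndarray
    jitter_pct: float
    shimmer_pct: float
    voiced_fraction: float

    def voiced_total_s(self) -> float:
        return sum(e - s for (s, e, lab) in self.voicing_intervals if lab == "voiced")

    def to_json(self, path) -> None:
        payload = {
            "label": self.label,
            "voicing_intervals": [[s, e, lab] for (s, e, lab) in self.voicing_intervals],
            "f0_times_s": self.f0_times_s.tolist(),
            "f0_hz": self.f0_hz.tolist(),
            "pulse_times_s": self.pulse_times_s.tolist(),
            "jitter_pct": self.jitter_pct,
            "shimmer_pct": self.shimmer_pct,
            "voiced_fraction": self.voiced_fraction,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            label=d["label"],
            voicing_intervals=[tuple(iv) for iv in d["voicing_intervals"]],
            f0_times_s=np.array(d["f0_times_s"]),
            f0_hz=np.array(d["f0_hz"]),
            pulse_times_s=np.array(d["pulse_times_s"]),
            jitter_pct=d["jitter_pct"],
            shimmer_pct=d["shimmer_pct"],
            voiced_fraction=d["voiced_fraction"],
        )


def _lognormal(rng, mean, cv, size):
    """Log-normal draws with the given arithmetic mean and coefficient of variation."""
    cv = max(cv, 1e-6)
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(max(mean, 1e-6)) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _partition_samples(rng, total: int, mean_s: float, cv: float, sr: int) -> list[int]:
    """Split ``total`` samples into log-normal pieces summing exactly to total."""
    if total <= 0:
        return []
    draws = []
    acc = 0
    while acc < total:
        d = max(1, int(round(_lognormal(rng, mean_s, cv, 1)[0] * sr)))
        draws.append(d)
        acc += d
    draws[-1] -= acc - total
    if draws[-1] <= 0:
        last = draws.pop()
        if draws:
            draws[-1] += last
    return draws


def _resonator(f_hz: float, bw_hz: float, sr: int):
    """Second-order all-pole resonator coefficients."""
    r = np.exp(-np.pi * bw_hz / sr)
    theta = 2.0 * np.pi * f_hz / sr
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    return [1.0 - r], a


def _f0_contour(rng, block: ClassBlock, n_grid: int, grid_s: float) -> np.ndarray:
    """Smooth pitch wander around the block mean, clipped to the range.

    An AR(1) walk (correlation time 1.5 s) sets the slow intonation
    movement; Gaussian smoothing (sigma 100 ms) removes grid-scale
    roughness so the contour's cycle-to-cycle drift stays an order of
    magnitude below typical programmed jitter — as in natural intonation,
    where drift and cycle perturbation are separate phenomena.
    """
    tau = 1.5  # correlation time, s
    a = np.exp(-grid_s / tau)
    sd = block.f0_range_hz / 4.0
    x = np.empty(n_grid)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, sd * np.sqrt(1 - a * a), n_grid)
    for i in range(1, n_grid):
        x[i] = a * x[i - 1] + eps[i]
    x = gaussian_filter1d(x, 0.1 / grid_s)
    s = np.std(x)
    if s > 0:
        x *= sd / s
    return np.clip(block.f0_mean_hz + x, block.f0_mean_hz - block.f0_range_hz / 2,
                   block.f0_mean_hz + block.f0_range_hz / 2)


def generate_segment(
    block: ClassBlock,
    segment_length_s: float = 60.0,
    sample_rate: int = 16_000,
    seed=0,
) -> tuple[AudioSignal, GroundTruth]:
    """Synthesize one segment and its exact annotations.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    block.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sr = sample_rate
    ns = int(round(segment_length_s * sr))

    # --- sample budget: voiced + breaks + pauses == ns exactly -------------
    V = int(round(block.voiced_fraction * ns))
    voiced_minutes = V / sr / 60.0
    n_breaks = int(round(block.voice_break_rate_per_min * voiced_minutes))
    break_lens = [int(round(d * sr)) for d in rng.uniform(0.08, 0.20, n_breaks)]
    B = sum(break_lens)
    if B > 0.2 * V:  # keep breaks a small perturbation of the voiced budget
        break_lens = break_lens[: max(1, int(len(break_lens) * 0.2 * V / B))]
        B = sum(break_lens)
    P = ns - V - B
    if P <= 0:
        raise InputError("voiced fraction and break rate leave no room for pauses")

    utt_lens = _partition_samples(rng, V, block.utterance_mean_s, 0.5, sr)
    pause_lens = _partition_samples(rng, P, block.pause_mean_s, block.pause_cv, sr)
    # breaks go into the longest utterances
    breaks_per_utt = [[] for _ in utt_lens]
    order = np.argsort(utt_lens)[::-1]
    for j, blen in enumerate(break_lens):
        breaks_per_utt[order[j % max(1, len(utt_lens))]].append(blen)

    # --- global f0 grid ----------------------------------------------------
    grid_s = 0.010
    n_grid = int(np.ceil(segment_length_s / grid_s)) + 2
    f0_grid = _f0_contour(rng, block, n_grid, grid_s)

    sigma_j = block.jitter_pct / 100.0 / _LOCAL_FACTOR
    sigma_s = block.shimmer_pct / 100.0 / _LOCAL_FACTOR

    x = np.zeros(ns)
    intervals: list[tuple[float, float, str]] = []
    pulse_times: list[float] = []
    pos = 0  # write cursor, samples

    # lay out: pause, utterance, pause, utterance, ...
    n_items = len(utt_lens) + len(pause_lens)
    pi, ui = 0, 0
    take_pause = True
    while pi < len(pause_lens) or ui < len(utt_lens):
        if take_pause and pi < len(pause_lens):
            plen = pause_lens[pi]
            intervals.append((pos / sr, (pos + plen) / sr, "unvoiced"))
            pos += plen
            pi += 1
        elif ui < len(utt_lens):
            ulen = utt_lens[ui]
            ubreaks = breaks_per_utt[ui]
            pos = _render_utterance(
                x, pos, ulen, ubreaks, block, f0_grid, grid_s, sigma_j, sigma_s,
                sr, rng, intervals, pulse_times,
            )
            ui += 1
        take_pause = not take_pause
        if pi >= len(pause_lens) and ui >= len(utt_lens):
            break
    del n_items

    # --- level, formant-independent per-segment normalization, noise -------
    speech_rms = np.sqrt(np.mean(x[x != 0] ** 2)) if np.any(x != 0) else 1.0
    noise = rng.normal(0.0, speech_rms * 10 ** (block.noise_floor_db / 20.0), ns)
    y = x + noise
    peak = np.max(np.abs(y))
    if peak > 0:
        y = 0.95 * y / peak

    f0_times = np.arange(n_grid) * grid_s
    voiced_mask_grid = np.zeros(n_grid, dtype=bool)
    for (s, e, lab) in intervals:
        if lab == "voiced":
            voiced_mask_grid |= (f0_times >= s) & (f0_times < e)
    truth = GroundTruth(
        label="",
        voicing_intervals=intervals,
        f0_times_s=f0_times[voiced_mask_grid],
        f0_hz=f0_grid[voiced_mask_grid],
        pulse_times_s=np.array(pulse_times),
        jitter_pct=block.jitter_pct,
        shimmer_pct=block.shimmer_pct,
        # breaks are budgeted outside the voiced total, so V/ns is exact
        voiced_fraction=V / ns,
    )
    return AudioSignal(y, sr), truth


def _render_utterance(x, pos, ulen, ubreaks, block, f0_grid, grid_s, sigma_j, sigma_s,
                      sr, rng, intervals, pulse_times) -> int:
    """Render one utterance (voiced chunks separated by break silences) at ``pos``."""
    # split the voiced budget of this utterance into len(ubreaks)+1 chunks
    n_chunks = len(ubreaks) + 1
    cuts = np.sort(rng.uniform(0.25, 0.75, n_chunks - 1)) if n_chunks > 1 else np.array([])
    chunk_lens = np.diff(np.concatenate([[0.0], cuts, [1.0]])) * ulen
    chunk_lens = np.maximum(1, np.round(chunk_lens).astype(int))
    chunk_lens[np.argmax(chunk_lens)] += ulen - chunk_lens.sum()
    chunk_lens = np.maximum(1, chunk_lens)
    chunk_lens[np.argmax(chunk_lens)] += ulen - chunk_lens.sum()

    # per-utterance vowel: three formant resonators + spectral tilt
    formants = (rng.uniform(350, 850), rng.uniform(1000, 1900), rng.uniform(2200, 2900))
    bws = (80.0, 120.0, 160.0)
    tilt_rho = np.clip(np.abs(block.spectral_tilt_db_oct) / 24.0 * 0.6 + 0.3, 0.0, 0.97)

    for ci, clen in enumerate(chunk_lens):
        if clen < 2:
            pos += int(clen)
            continue
        excitation = np.zeros(int(clen))
        t = 0.0  # seconds within chunk
        chunk_start_s = pos / sr
        while True:
            gi = min(int((chunk_start_s + t) / grid_s), len(f0_grid) - 1)
            f0 = f0_grid[gi]
            period = (1.0 + sigma_j * rng.normal()) / f0
            period = max(period, 0.3 / f0)
            t_next = t + period
            if t_next * sr >= clen - 1:
                break
            amp = max(0.05, 1.0 + sigma_s * rng.normal())
            # fractional-sample impulse placement keeps quantization jitter low
            s_frac = t_next * sr
            s0 = int(s_frac)
            frac = s_frac - s0
            excitation[s0] += amp * (1.0 - frac)
            excitation[s0 + 1] += amp * frac
            pulse_times.append(chunk_start_s + t_next)
            t = t_next
        v = excitation
        for f, bw in zip(formants, bws):
            b, a = _resonator(f, bw, sr)
            v = lfilter(b, a, v)
        v = lfilter([1.0 - tilt_rho], [1.0, -tilt_rho], v)
        rms = np.sqrt(np.mean(v ** 2))
        if rms > 0:
            v = v / rms * 0.15
        x[pos:pos + len(v)] = v
        intervals.append((pos / sr, (pos + int(clen)) / sr, "voiced"))
        pos += int(clen)
        if ci < len(ubreaks):
            blen = ubreaks[ci]
            intervals.append((pos / sr, (pos + blen) / sr, "unvoiced"))
            pos += blen
    return pos


@dataclass
class CohortSegment:
    segment_id: str
    label: str
    signal: AudioSignal
    truth: GroundTruth


def generate_cohort(spec: CohortSpec, out_dir=None) -> list[CohortSegment]:
    """Generate all segments of a cohort; optionally write WAV + manifest + truth.

    When ``out_dir`` is given, each segment is written as
    ``<id>.wav`` / ``<id>.truth.json`` and a ``manifest.csv`` with columns
    ``path,label`` is produced.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    segments: list[CohortSegment] = []
    for label in CLASSES:
        n = spec.n_segments.get(label, 0)
        block = spec.blocks[label]
        for i in range(n):
            child = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))
            sig, truth = generate_segment(block, spec.segment_length_s, spec.sample_rate, child)
            truth.label = label
            segments.append(CohortSegment(f"{label}_{i:03d}", label, sig, truth))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label"])
            for seg in segments:
                wav = out / f"{seg.segment_id}.wav"
                save_wav(wav, seg.signal)
                seg.truth.to_json(out / f"{seg.segment_id}.truth.json")
                writer.writerow([wav.name, seg.label])
    return segments
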