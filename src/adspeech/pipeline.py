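"""End-to-end feature extraction: waveform -> named feature row.

Glue between the signal-level modules and the tabular classification
stage; used by both the command-line tool and the test harness.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import audio_io, esa, etemp, fractal, ssf, vad
from .audio_io import AudioSignal
from .config import RunConfig
from .etemp import EmotionalTemperatureModel

logger = logging.getLogger(__name__)


def prepare_signal(signal: AudioSignal, cfg: RunConfig) -> AudioSignal:
    """Denoise according to the config (no-op when disabled)."""
    if cfg.audio.denoise:
        return audio_io.denoise(signal, cfg.audio.noise_profile_s, cfg.audio.over_subtraction)
    return signal


def extract_segment_features(
    signal: AudioSignal,
    cfg: RunConfig | None = None,
    et_model: EmotionalTemperatureModel | None = None,
) -> dict[str, float]:
    """All feature columns (``ssf.*``, ``fd.*``, ``esa.*`` and optionally ``et``)
    for one already-denoised analysis segment."""
    cfg = cfg or RunConfig()
    seg = vad.detect_voicing(
        signal,
        frame_length_s=cfg.vad.frame_length_s, hop_s=cfg.vad.hop_s,
        energy_floor_db=cfg.vad.energy_floor_db, zcr_split=cfg.vad.zcr_split,
        autocorr_threshold=cfg.vad.autocorr_threshold,
        min_interval_s=cfg.vad.min_interval_s, smooth_frames=cfg.vad.smooth_frames,
    )
    row: dict[str, float] = {}
    row.update(ssf.ssf_vector(
        signal, seg,
        n_bins=cfg.ssf.n_bins, relevance_quantile=cfg.ssf.relevance_quantile,
        evolution_window_s=cfg.ssf.evolution_window_s,
        frame_length_s=cfg.vad.frame_length_s, hop_s=cfg.vad.hop_s,
        median_filter=cfg.ssf.median_filter,
    ).to_row())
    row.update(fractal.fd_features(
        signal, window_s=cfg.fd.window_s, hop_s=cfg.fd.hop_s, kmax=cfg.fd.kmax,
    ).to_row())
    contour = esa.estimate_pitch(
        signal, fmin=cfg.pitch.fmin, fmax=cfg.pitch.fmax,
        frame_length_s=cfg.pitch.frame_length_s, hop_s=cfg.pitch.hop_s,
        voicing_threshold=cfg.pitch.voicing_threshold,
    )
    row.update(esa.esa_vector(signal, contour).to_row())
    if et_model is not None:
        res = etemp.emotional_temperature(signal, et_model)
        row["et"] = res.et
    return row


def extract_frame_training_set(
    segments: list[tuple[str, str, AudioSignal]],
    cfg: RunConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame features + binary frame labels for ET training.

    ``segments`` is (segment_id, class_label, signal); every frame of a
    control (CR) segment is labeled non-pathological, every frame of an
    impaired segment pathological (segment-label inheritance).
    Returns (X, y, segment_ids) over classifiable frames only.
    """
    cfg = cfg or RunConfig()
    bands = tuple(tuple(b) for b in cfg.et.bands_hz)
    Xs, ys, ids = [], [], []
    for seg_id, label, signal in segments:
        ff = etemp.frame_features(
            signal, frame_length_s=cfg.et.frame_length_s, hop_s=cfg.et.hop_s, bands_hz=bands,
        )
        X = ff.X[ff.valid]
        frame_label = etemp.NON_PATHOLOGICAL if label == "CR" else etemp.PATHOLOGICAL
        Xs.append(X)
        ys.append(np.full(len(X), frame_label))
        ids.append(np.full(len(X), seg_id, dtype=object))
    return np.concatenate(Xs), np.concatenate(ys), np.concatenate(ids)


def build_feature_table(
    segments: list[tuple[str, str, AudioSignal]],
    cfg: RunConfig | None = None,
    et_model: EmotionalTemperatureModel | None = None,
) -> pd.DataFrame:
    """Per-segment feature table with a ``label`` column, indexed by segment id."""
    cfg = cfg or RunConfig()
    rows = {}
    labels = {}
    for seg_id, label, signal in segments:
        rows[seg_id] = extract_segment_features(signal, cfg, et_model)
        labels[seg_id] = label
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["label"] = pd.Series(labels)
    return table
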