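"""End-to-end detection: each lead is conditioned, segmented by the
network in non-overlapping 30 s windows, decoded into beat lists, and
the per-lead lists are fused by majority vote.

Window logits are stitched back into one record-global probability
matrix before beat extraction, so region scanning never sees window
seams and beat indices are record-global by construction.  The zero-pad
tail of the final window is trimmed before extraction, and flat-signal
(pseudo) beats are cancelled per lead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ECGRecord, RunConfig
from .postprocess import (PostprocessConfig, cancel_pseudobeats,
                          extract_beats, majority_vote, merge_beat_lists,
                          softmax_masks)
from .preprocess import preprocess_signal, window_30s


@dataclass
class PipelineResult:
    per_channel: list                  # one BeatAnnotation list per lead
    merged: list                       # majority-vote fused list
    fs: float                          # rate the beat indices refer to
    provenance: dict = field(default_factory=dict)


def _postprocess_cfg(cfg: RunConfig) -> PostprocessConfig:
    return PostprocessConfig(
        threshold=cfg.threshold, termination_gap=cfg.termination_gap,
        min_run=cfg.min_run, merge_window_ms=cfg.merge_window_ms,
        flatline_window_s=cfg.flatline_window_s,
        flatline_floor_mv=cfg.flatline_floor_mv,
        vote_tolerance_ms=cfg.vote_tolerance_ms)


def segment_channel(signal_125, model, cfg: RunConfig,
                    whole_record: bool = False) -> np.ndarray:
    """Class-probability matrix (L x 3) for one preprocessed lead."""
    if whole_record:
        return softmax_masks(model.predict_logits(signal_125))
    wlen = int(round(cfg.window_seconds * cfg.target_fs))
    parts = []
    for w in window_30s(signal_125, cfg.target_fs, cfg.window_seconds):
        probs = softmax_masks(model.predict_logits(w.samples))
        if w.pad_len:
            probs = probs[:wlen - w.pad_len]
        parts.append(probs)
    return np.vstack(parts) if parts else np.zeros((0, 3))


def detect_channel(signal_125, model, cfg: RunConfig,
                   whole_record: bool = False):
    """Beat list for one preprocessed lead."""
    probs = segment_channel(signal_125, model, cfg, whole_record)
    pcfg = _postprocess_cfg(cfg)
    normal = extract_beats(probs[:, 1], pcfg)
    pvc = extract_beats(probs[:, 2], pcfg)
    beats = merge_beat_lists(normal, pvc, probs, cfg.target_fs, pcfg)
    return cancel_pseudobeats(beats, signal_125, cfg.target_fs, pcfg)


def run_detection(record: ECGRecord, model, cfg: RunConfig | None = None,
                  whole_record: bool = False) -> PipelineResult:
    """Full multi-lead detection on one record."""
    cfg = cfg or RunConfig()
    min_len_s = model.cfg.min_input_len / cfg.target_fs
    if record.duration_s < min_len_s:
        raise ValueError(
            f"record of {record.duration_s:.2f} s is shorter than the "
            f"minimum model input of {min_len_s:.2f} s")
    per_channel = []
    for ch in range(record.n_leads):
        x = preprocess_signal(record.samples[ch], record.fs,
                              cfg.mains_freq, cfg.target_fs)
        per_channel.append(detect_channel(x, model, cfg, whole_record))
    merged = majority_vote(per_channel, cfg.target_fs, _postprocess_cfg(cfg))
    return PipelineResult(
        per_channel=per_channel, merged=merged, fs=cfg.target_fs,
        provenance={"record_id": record.record_id,
                    "n_leads": record.n_leads,
                    "whole_record": whole_record,
                    "model_params": model.count_parameters()})
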