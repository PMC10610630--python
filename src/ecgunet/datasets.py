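"""Dataset assembly: turn records + annotations into training windows.

Shared by the CLI ``train`` command, the test suite and the acceptance
experiment: every record is preprocessed to 125 Hz, annotation indices
are mapped onto the resampled grid, the record is cut into 30 s windows
and each window gets its segmentation mask.
"""

from __future__ import annotations

import numpy as np

from .io import ECGRecord, RunConfig
from .labeling import LabelConfig, build_mask, window_beats
from .preprocess import preprocess_signal, resample_index, window_30s


def record_to_windows(record: ECGRecord, beats, cfg: RunConfig | None = None,
                      lead: int = 0, label_cfg: LabelConfig | None = None):
    """One record -> (windows (Nw, L), masks (Nw, L)) at 125 Hz."""
    cfg = cfg or RunConfig()
    label_cfg = label_cfg or LabelConfig(
        normal_pre_ms=cfg.normal_pre_ms, normal_post_ms=cfg.normal_post_ms,
        pvc_pre_ms=cfg.pvc_pre_ms, pvc_post_ms=cfg.pvc_post_ms)
    x = preprocess_signal(record.samples[lead], record.fs,
                          cfg.mains_freq, cfg.target_fs)
    idx = resample_index([b.sample_index for b in beats],
                         record.fs, cfg.target_fs)
    from .io import BeatAnnotation
    beats_125 = [BeatAnnotation(int(i), b.beat_class)
                 for i, b in zip(idx, beats) if 0 <= i < len(x)]
    wlen = int(round(cfg.window_seconds * cfg.target_fs))
    wins, masks = [], []
    for w in window_30s(x, cfg.target_fs, cfg.window_seconds):
        local = window_beats(beats_125, w.start_sample, wlen - w.pad_len)
        mask = build_mask(local, wlen, cfg.target_fs, label_cfg)
        wins.append(w.samples)
        masks.append(mask)
    return np.asarray(wins, dtype=np.float32), np.asarray(masks, dtype=np.int8)


def records_to_training_set(records_with_beats, cfg: RunConfig | None = None):
    """Stack (record, beats) pairs into one training array pair."""
    all_w, all_m = [], []
    for record, beats in records_with_beats:
        w, m = record_to_windows(record, beats, cfg)
        all_w.append(w)
        all_m.append(m)
    return np.concatenate(all_w), np.concatenate(all_m)
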