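"""Segmentation-mask construction and training-set composition.

Beats become per-sample class labels: 0 background, 1 normal, 2 PVC.
A normal beat paints the samples from 100 ms before to 100 ms after its
R peak (~200 ms, 25 samples at 125 Hz); a PVC paints 100 ms before to
150 ms after, the longer tail covering the wide ventricular complex.
Where label windows overlap, the PVC class wins — it is the minority
class of clinical interest.

Also houses the training-set composition policies: rejection of windows
containing unclassifiable beats, Bernoulli subsampling of PVC-free
segments, and PVC oversampling weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BeatAnnotation, BeatClass

BACKGROUND, NORMAL_LABEL, PVC_LABEL = 0, 1, 2


@dataclass
class LabelConfig:
    normal_pre_ms: float = 100.0
    normal_post_ms: float = 100.0
    pvc_pre_ms: float = 100.0
    pvc_post_ms: float = 150.0

    def __post_init__(self):
        if min(self.normal_pre_ms, self.normal_post_ms,
               self.pvc_pre_ms, self.pvc_post_ms) < 0:
            raise ValueError("label windows must be non-negative")


# Rounding: 100 ms at 125 Hz is 12.5 samples.  Round-half-to-even gives
# 12 on each side, so the inclusive normal window spans 25 samples —
# matching the 200 ms ~ 25 sample correspondence of the first network
# layer's receptive field.  (Half-away-from-zero would give 27.)
def ms_to_samples(ms: float, fs: float) -> int:
    return int(np.rint(ms * fs / 1000.0))


def build_mask(beats, length: int, fs: float,
               cfg: LabelConfig | None = None) -> np.ndarray:
    """Paint per-sample labels for a window of ``length`` samples."""
    cfg = cfg or LabelConfig()
    labels = np.zeros(length, dtype=np.int8)
    for b in beats:
        if not 0 <= b.sample_index < length:
            raise ValueError(
                f"beat at {b.sample_index} outside signal of length {length}")
    # paint normals first so PVC windows overwrite at overlaps
    for want, pre, post, lab in (
            (BeatClass.NORMAL, cfg.normal_pre_ms, cfg.normal_post_ms, NORMAL_LABEL),
            (BeatClass.PVC, cfg.pvc_pre_ms, cfg.pvc_post_ms, PVC_LABEL)):
        w_pre, w_post = ms_to_samples(pre, fs), ms_to_samples(post, fs)
        for b in beats:
            if b.beat_class is not want:
                continue
            lo = max(b.sample_index - w_pre, 0)
            hi = min(b.sample_index + w_post, length - 1)
            labels[lo:hi + 1] = lab
    return labels


def mask_to_onehot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """One-hot (length x n_classes) float matrix from integer labels."""
    return np.eye(n_classes, dtype=np.float32)[np.asarray(labels, dtype=int)]


def reject_window(symbols) -> bool:
    """True iff the window holds any beat symbol other than N or V.

    Windows with unclassifiable or other-class beats are excluded from
    training rather than mislabeled as background.
    """
    return any(s not in ("N", "V") for s in symbols)


def window_beats(beats, start: int, length: int):
    """Beats falling in [start, start+length), re-indexed window-locally."""
    return [BeatAnnotation(b.sample_index - start, b.beat_class)
            for b in beats if start <= b.sample_index < start + length]


def subsample_segments(segments, has_pvc, normal_keep_frac: float = 0.01,
                       pvc_keep_frac: float = 1.0, seed: int = 0):
    """Bernoulli segment subsampling (Icentia-style composition policy).

    Keeps each PVC-containing segment with probability ``pvc_keep_frac``
    and each PVC-free segment with probability ``normal_keep_frac``.
    ``has_pvc`` is a boolean per segment; returns the kept subset (list).
    """
    if not 0 <= normal_keep_frac <= 1 or not 0 <= pvc_keep_frac <= 1:
        raise ValueError("keep fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    segments = list(segments)
    u = rng.random(len(segments))
    out = []
    for seg, pvc, ui in zip(segments, has_pvc, u):
        p = pvc_keep_frac if pvc else normal_keep_frac
        if ui < p:
            out.append(seg)
    return out


def oversample_pvc(has_pvc, target_pvc_window_frac: float = 0.5):
    """Per-window sampling weights achieving the target PVC-window share.

    Returns weights (normalized to sum 1) such that drawing windows with
    replacement yields PVC-containing windows with expected fraction
    ``target_pvc_window_frac``.  No window is dropped.
    """
    has_pvc = np.asarray(has_pvc, dtype=bool)
    n_pvc = int(has_pvc.sum())
    n_neg = int((~has_pvc).sum())
    if n_pvc == 0:
        raise ValueError(
            "no PVC-containing windows in the training set; generate data "
            "with pvc_probability > 0 or lower target_pvc_window_frac")
    if n_neg == 0:
        return np.full(len(has_pvc), 1.0 / len(has_pvc))
    t = float(target_pvc_window_frac)
    w = np.where(has_pvc, t / n_pvc, (1.0 - t) / n_neg)
    return w / w.sum()
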