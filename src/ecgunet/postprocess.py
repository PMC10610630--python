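"""Mask-to-beat-list post-processing and multi-lead fusion.

The network's L x 3 logits become three probability masks via a rowwise
softmax.  Each beat-class mask is scanned left to right: a region opens
when the probability reaches the 0.5 threshold and closes once it stays
below threshold for at least 2 consecutive samples (or the signal ends).
Regions of at least 5 samples (40 ms at 125 Hz) are accepted; the
midpoint between onset and termination becomes the beat location.  The
normal and PVC lists are then merged, beats sitting on flat (non-ECG)
signal are cancelled, and per-lead lists are fused by majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BeatAnnotation, BeatClass


@dataclass
class PostprocessConfig:
    threshold: float = 0.5
    termination_gap: int = 2      # consecutive sub-threshold samples ending a region
    min_run: int = 5              # minimum region span in samples (40 ms at 125 Hz)
    merge_window_ms: float = 150.0
    flatline_window_s: float = 1.0
    flatline_floor_mv: float = 0.05
    vote_tolerance_ms: float = 150.0

    def __post_init__(self):
        if self.min_run < 1 or self.termination_gap < 1:
            raise ValueError("min_run and termination_gap must be >= 1")


def softmax_masks(logits: np.ndarray) -> np.ndarray:
    """Rowwise numerically-stable softmax: L x C logits -> L x C probs."""
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def extract_beats(mask: np.ndarray, cfg: PostprocessConfig | None = None) -> list[int]:
    """Scan one class mask into beat sample indices (see module docstring)."""
    cfg = cfg or PostprocessConfig()
    mask = np.asarray(mask, dtype=np.float64)
    if mask.size and (mask.min() < 0 or mask.max() > 1):
        raise ValueError("mask values must lie in [0, 1]")
    above = mask >= cfg.threshold
    beats = []
    i = 0
    n = len(mask)
    while i < n:
        if not above[i]:
            i += 1
            continue
        onset = i
        last_above = i
        gap = 0
        j = i + 1
        while j < n:
            if above[j]:
                last_above = j
                gap = 0
            else:
                gap += 1
                if gap >= cfg.termination_gap:
                    break
            j += 1
        end = last_above
        if end - onset + 1 >= cfg.min_run:
            beats.append((onset + end) // 2)
        i = j + 1
    return beats


def merge_beat_lists(normal_beats, pvc_beats, probs: np.ndarray,
                     fs: float, cfg: PostprocessConfig | None = None):
    """Merge the two class lists into one sorted BeatAnnotation list.

    When a normal and a PVC beat fall within the merge window of one
    another, only the one whose own class probability at its location is
    higher survives.
    """
    cfg = cfg or PostprocessConfig()
    win = cfg.merge_window_ms * fs / 1000.0
    cands = ([(i, BeatClass.NORMAL, probs[i, 1]) for i in normal_beats]
             + [(i, BeatClass.PVC, probs[i, 2]) for i in pvc_beats])
    cands.sort(key=lambda c: (c[0], c[1].value))
    keep = [True] * len(cands)
    for a in range(len(cands)):
        for b in range(a + 1, len(cands)):
            if cands[b][0] - cands[a][0] > win:
                break
            if cands[a][1] is cands[b][1]:
                continue
            if not (keep[a] and keep[b]):
                continue
            # conflict: drop the lower-probability beat
            if cands[a][2] >= cands[b][2]:
                keep[b] = False
            else:
                keep[a] = False
    return [BeatAnnotation(i, c) for (i, c, _), k in zip(cands, keep) if k]


def cancel_pseudobeats(beats, signal: np.ndarray, fs: float,
                       cfg: PostprocessConfig | None = None):
    """Drop beats whose surrounding signal is flat (no ECG present).

    A beat is removed iff the standard deviation of the signal in a
    +-flatline_window_s neighborhood falls below the amplitude floor —
    e.g. detections after electrode removal at the end of a recording.
    """
    cfg = cfg or PostprocessConfig()
    half = int(round(cfg.flatline_window_s * fs))
    signal = np.asarray(signal, dtype=np.float64)
    out = []
    for b in beats:
        lo = max(b.sample_index - half, 0)
        hi = min(b.sample_index + half + 1, len(signal))
        if np.std(signal[lo:hi]) >= cfg.flatline_floor_mv:
            out.append(b)
    return out


def majority_vote(per_channel_beats, fs: float,
                  cfg: PostprocessConfig | None = None):
    """Fuse per-lead beat lists: greedy proximity clustering + majority.

    Beats across channels within the vote tolerance cluster together; a
    cluster survives iff it holds beats from more than half the
    channels.  Its position is the median of member positions, its class
    the member majority (ties go to PVC, the clinically conservative
    choice).
    """
    cfg = cfg or PostprocessConfig()
    lists = [list(ch) for ch in per_channel_beats]
    n_ch = len(lists)
    if n_ch == 0:
        raise ValueError("majority vote needs at least one channel")
    if n_ch == 1:
        return sorted(lists[0])
    tol = cfg.vote_tolerance_ms * fs / 1000.0
    events = sorted(
        ((b.sample_index, ch, b) for ch, lst in enumerate(lists) for b in lst),
        key=lambda e: e[0])
    clusters = []
    for pos, ch, b in events:
        if clusters and pos - clusters[-1]["last"] <= tol and ch not in clusters[-1]["chans"]:
            clusters[-1]["members"].append(b)
            clusters[-1]["chans"].add(ch)
            clusters[-1]["last"] = pos
        else:
            clusters.append({"members": [b], "chans": {ch}, "last": pos})
    out = []
    need = n_ch // 2 + 1
    for cl in clusters:
        if len(cl["chans"]) < need:
            continue
        poss = sorted(m.sample_index for m in cl["members"])
        pos = int(np.median(poss))
        n_pvc = sum(m.beat_class is BeatClass.PVC for m in cl["members"])
        cls = BeatClass.PVC if n_pvc * 2 >= len(cl["members"]) else BeatClass.NORMAL
        out.append(BeatAnnotation(pos, cls))
    out.sort()
    return out
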