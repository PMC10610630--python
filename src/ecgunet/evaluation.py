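"""Beat matching and Se/Sp/balanced-accuracy scoring.

A predicted beat matches a reference beat of the same class when it
falls within the matching tolerance (default +-75 ms, a 150 ms interval
centered on the reference); assignment is greedy nearest-first and
one-to-one.  Reference beats in the first or last 0.2 s of a recording
are disregarded.  Per class:

* TP — matched reference beats;
* FN — unmatched eligible reference beats;
* FP — unmatched predictions;
* TN — eligible reference beats of the *other* classes with no
  prediction of this class within tolerance (the cross-class
  true-negative convention for event detection);

and Se = TP/(TP+FN), Sp = TN/(TN+FP), BA = (Se+Sp)/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io import BeatAnnotation, BeatClass


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __iadd__(self, other):
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        self.tn += other.tn
        return self


@dataclass
class EvalCounts:
    per_class: dict = field(default_factory=lambda: {
        BeatClass.NORMAL: ClassCounts(), BeatClass.PVC: ClassCounts()})

    def __iadd__(self, other):
        for c in self.per_class:
            self.per_class[c] += other.per_class[c]
        return self


@dataclass
class ClassMetrics:
    se: float
    sp: float
    ba: float


def _check_sorted(beats, name):
    idx = [b.sample_index for b in beats]
    if any(b < a for a, b in zip(idx, idx[1:])):
        raise ValueError(f"{name} beat list must be sorted")


def _greedy_match(ref_idx, pred_idx, tol):
    """Nearest-first one-to-one assignment; returns set of matched ref
    positions (by list index) and matched pred list indices."""
    pairs = []
    for ri, r in enumerate(ref_idx):
        for pi, p in enumerate(pred_idx):
            d = abs(p - r)
            if d <= tol:
                pairs.append((d, ri, pi))
    pairs.sort()
    used_r, used_p = set(), set()
    for d, ri, pi in pairs:
        if ri in used_r or pi in used_p:
            continue
        used_r.add(ri)
        used_p.add(pi)
    return used_r, used_p


def match_beats(predicted, reference, fs: float, tolerance_ms: float = 75.0,
                edge_exclude_s: float = 0.2,
                record_duration_s: float | None = None) -> EvalCounts:
    """Count TP/FP/FN/TN per class (see module docstring)."""
    predicted, reference = list(predicted), list(reference)
    _check_sorted(predicted, "predicted")
    _check_sorted(reference, "reference")
    if record_duration_s is None:
        last = max([b.sample_index for b in predicted + reference], default=0)
        record_duration_s = (last + 1) / fs
    lo = edge_exclude_s * fs
    hi = record_duration_s * fs - edge_exclude_s * fs
    eligible = [b for b in reference if lo <= b.sample_index <= hi]
    tol = tolerance_ms * fs / 1000.0
    counts = EvalCounts()
    for cls in (BeatClass.NORMAL, BeatClass.PVC):
        ref_c = [b.sample_index for b in eligible if b.beat_class is cls]
        pred_c = [b.sample_index for b in predicted if b.beat_class is cls]
        used_r, used_p = _greedy_match(ref_c, pred_c, tol)
        cc = counts.per_class[cls]
        cc.tp = len(used_r)
        cc.fn = len(ref_c) - len(used_r)
        cc.fp = len(pred_c) - len(used_p)
        # TN: eligible reference beats of other classes with no class-c
        # prediction within tolerance
        others = [b.sample_index for b in eligible if b.beat_class is not cls]
        tn = 0
        for o in others:
            if not any(abs(p - o) <= tol for p in pred_c):
                tn += 1
        cc.tn = tn
    return counts


def compute_metrics(counts: EvalCounts) -> dict:
    """Se/Sp/BA per class; zero denominators yield NaN, never silent 0."""
    out = {}
    for cls, cc in counts.per_class.items():
        se = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) else math.nan
        sp = cc.tn / (cc.tn + cc.fp) if (cc.tn + cc.fp) else math.nan
        ba = (se + sp) / 2.0
        out[cls] = ClassMetrics(se=se, sp=sp, ba=ba)
    return out


def balanced_accuracy(se: float, sp: float) -> float:
    """BA = (Se + Sp) / 2."""
    return (se + sp) / 2.0


def evaluate_record(predicted, reference, fs, tolerance_ms=75.0,
                    edge_exclude_s=0.2, record_duration_s=None):
    """Convenience: match then score one record."""
    counts = match_beats(predicted, reference, fs, tolerance_ms,
                         edge_exclude_s, record_duration_s)
    return counts, compute_metrics(counts)


def pool_counts(counts_list) -> EvalCounts:
    """Micro-average: sum counts over records before computing metrics."""
    total = EvalCounts()
    for c in counts_list:
        total += c
    return total
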