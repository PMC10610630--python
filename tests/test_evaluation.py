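"""Beat matching against an all-pairs oracle; metric arithmetic."""

import math

import numpy as np
import pytest

from ecgunet.evaluation import (balanced_accuracy, compute_metrics,
                                evaluate_record, match_beats, pool_counts)
from ecgunet.io import BeatAnnotation, BeatClass

FS = 125.0


def oracle_match(ref, pred, tol):
    """All-pairs nearest-first one-to-one assignment, written
    independently: enumerate every pair, sort by distance, assign."""
    pairs = sorted((abs(p - r), ri, pi)
                   for ri, r in enumerate(ref)
                   for pi, p in enumerate(pred) if abs(p - r) <= tol)
    ur, up = set(), set()
    for _, ri, pi in pairs:
        if ri not in ur and pi not in up:
            ur.add(ri)
            up.add(pi)
    return len(ur)


class TestMatchBeats:
    def test_perfect_predictions(self, beats_factory):
        beats = beats_factory([(500, "N"), (1000, "V"), (1500, "N")])
        counts = match_beats(beats, beats, FS, record_duration_s=30.0)
        n = counts.per_class[BeatClass.NORMAL]
        v = counts.per_class[BeatClass.PVC]
        assert (n.tp, n.fp, n.fn) == (2, 0, 0)
        assert (v.tp, v.fp, v.fn) == (1, 0, 0)

    def test_edge_beats_disregarded(self, beats_factory):
        # reference PVC at 0.1 s of a 30 s record: excluded entirely
        ref = beats_factory([(int(0.1 * FS), "V"), (1000, "N")])
        counts = match_beats([], ref, FS, record_duration_s=30.0)
        v = counts.per_class[BeatClass.PVC]
        assert (v.tp, v.fn) == (0, 0)

    def test_match_within_75ms(self, beats_factory):
        ref = beats_factory([(1250, "N")])          # 10.000 s
        pred = beats_factory([(1256, "N")])         # 10.048 s -> |d| 48 ms
        counts = match_beats(pred, ref, FS, record_duration_s=30.0)
        assert counts.per_class[BeatClass.NORMAL].tp == 1

    def test_beyond_tolerance_no_match(self, beats_factory):
        ref = beats_factory([(1250, "N")])
        pred = beats_factory([(1260, "N")])         # 80 ms away
        counts = match_beats(pred, ref, FS, record_duration_s=30.0)
        n = counts.per_class[BeatClass.NORMAL]
        assert (n.tp, n.fp, n.fn) == (0, 1, 1)

    def test_one_to_one_assignment(self, beats_factory):
        ref = beats_factory([(1000, "N")])
        pred = beats_factory([(995, "N"), (1005, "N")])
        counts = match_beats(pred, ref, FS, record_duration_s=30.0)
        n = counts.per_class[BeatClass.NORMAL]
        assert (n.tp, n.fp) == (1, 1)

    def test_cross_class_true_negatives(self, beats_factory):
        # a normal reference far from any PVC prediction counts as a
        # PVC true negative
        ref = beats_factory([(1000, "N"), (2000, "V")])
        pred = beats_factory([(1000, "N"), (2000, "V")])
        counts = match_beats(pred, ref, FS, record_duration_s=30.0)
        assert counts.per_class[BeatClass.PVC].tn == 1
        assert counts.per_class[BeatClass.NORMAL].tn == 1

    def test_unsorted_rejected(self):
        bad = [BeatAnnotation(100, BeatClass.NORMAL),
               BeatAnnotation(50, BeatClass.NORMAL)]
        with pytest.raises(ValueError):
            match_beats(bad, [], FS)

    def test_shift_invariance(self, beats_factory):
        ref = beats_factory([(1000, "N"), (2000, "V"), (3000, "N")])
        pred = beats_factory([(1004, "N"), (1996, "V")])
        c1 = match_beats(pred, ref, FS, record_duration_s=60.0)
        shift = 500
        ref2 = [BeatAnnotation(b.sample_index + shift, b.beat_class)
                for b in ref]
        pred2 = [BeatAnnotation(b.sample_index + shift, b.beat_class)
                 for b in pred]
        c2 = match_beats(pred2, ref2, FS, record_duration_s=60.0 + shift / FS)
        for cls in BeatClass:
            assert c1.per_class[cls].tp == c2.per_class[cls].tp
            assert c1.per_class[cls].fn == c2.per_class[cls].fn

    def test_swap_exchanges_fp_and_fn(self, beats_factory):
        ref = beats_factory([(1000, "N"), (2000, "N"), (3000, "N")])
        pred = beats_factory([(1003, "N"), (2500, "N")])
        a = match_beats(pred, ref, FS, record_duration_s=60.0)
        b = match_beats(ref, pred, FS, record_duration_s=60.0)
        n_a, n_b = a.per_class[BeatClass.NORMAL], b.per_class[BeatClass.NORMAL]
        assert n_a.tp == n_b.tp
        assert n_a.fp == n_b.fn and n_a.fn == n_b.fp

    @pytest.mark.parametrize("seed", range(3))
    def test_tp_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tol = 75.0 * FS / 1000.0
        for _ in range(333):
            ref = np.unique(rng.integers(100, 5000, size=rng.integers(1, 15)))
            pred = np.unique(rng.integers(100, 5000, size=rng.integers(1, 15)))
            refs = [BeatAnnotation(int(i), BeatClass.NORMAL) for i in ref]
            preds = [BeatAnnotation(int(i), BeatClass.NORMAL) for i in pred]
            counts = match_beats(preds, refs, FS, record_duration_s=60.0)
            assert counts.per_class[BeatClass.NORMAL].tp == \
                oracle_match(list(ref), list(pred), tol)


class TestMetrics:
    def test_sensitivity_arithmetic(self):
        counts = match_beats([], [], FS, record_duration_s=10.0)
        cc = counts.per_class[BeatClass.NORMAL]
        cc.tp, cc.fn = 9, 1
        cc.tn, cc.fp = 5, 0
        m = compute_metrics(counts)[BeatClass.NORMAL]
        assert m.se == pytest.approx(0.9)
        assert m.ba == pytest.approx((0.9 + 1.0) / 2)

    @pytest.mark.parametrize("se,sp,printed_ba", [
        # published QRS rows: (Se, Sp) -> BA
        (0.999, 0.997, 0.998), (0.999, 0.999, 0.999), (0.997, 0.992, 0.995),
        (0.893, 0.954, 0.924), (0.999, 0.983, 0.991), (0.997, 0.993, 0.995),
        # published PVC rows
        (0.966, 0.926, 0.946), (0.857, 0.972, 0.915),
        (0.881, 0.936, 0.909), (0.973, 0.950, 0.962), (0.932, 0.960, 0.946),
    ])
    def test_balanced_accuracy_regenerates_published_rows(self, se, sp,
                                                          printed_ba):
        assert abs(balanced_accuracy(se, sp) - printed_ba) <= 5.001e-4

    def test_inconsistent_published_row_recomputed_correctly(self):
        """One published PVC row (Se 0.991, Sp 0.976, BA listed as 0.986)
        is internally inconsistent: the definition BA = (Se + Sp) / 2
        gives 0.9835.  The arithmetic here follows the definition."""
        assert balanced_accuracy(0.991, 0.976) == pytest.approx(0.9835,
                                                                abs=1e-12)

    def test_zero_denominators_flagged_not_silent(self):
        counts = match_beats([], [], FS, record_duration_s=10.0)
        m = compute_metrics(counts)[BeatClass.PVC]
        assert math.isnan(m.se) and math.isnan(m.sp)

    def test_pooling_sums_counts(self, beats_factory):
        ref = beats_factory([(1000, "N")])
        c1, _ = evaluate_record(ref, ref, FS, record_duration_s=30.0)
        c2, _ = evaluate_record(ref, ref, FS, record_duration_s=30.0)
        pooled = pool_counts([c1, c2])
        assert pooled.per_class[BeatClass.NORMAL].tp == 2
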