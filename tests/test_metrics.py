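"""CLEAR-MOT, identity metrics, counting PRF and brightness."""

import itertools
import math

import numpy as np
import pytest

from beecount.counting import CountEvent
from beecount.geometry import Direction
from beecount.metrics import (
    average_brightness,
    clear_mot,
    count_prf,
    f1_score,
    idf1,
)
from beecount.tracker import BBox, TrackObservation, iou
from conftest import linear_scene


def obs(frame, tid, x, y, w=10.0, h=10.0):
    return TrackObservation(frame, tid, BBox(x, y, w, h))


class TestClearMot:
    def test_perfect_tracking(self):
        gt, _ = linear_scene(3, 20)
        s = clear_mot(gt, gt)
        assert (s.fn, s.fp, s.idsw) == (0, 0, 0)
        assert s.mota == 1.0 and s.idf1 == 1.0

    def test_miss_and_spurious_box(self):
        # 10 gt boxes; prediction misses one and adds one far away:
        # MOTA = 1 − (1 + 1 + 0)/10 = 0.8
        gt = [obs(f, 1, 2.0 * f, 50) for f in range(1, 11)]
        pred = [obs(f, 7, 2.0 * f, 50) for f in range(1, 11) if f != 4]
        pred.append(obs(6, 8, 300, 300))
        s = clear_mot(gt, pred)
        assert (s.fn, s.fp, s.idsw) == (1, 1, 0)
        assert s.mota == pytest.approx(0.8)

    def test_single_identity_switch(self):
        # one trajectory, id A for the first half, id B for the second
        gt = [obs(f, 1, 2.0 * f, 50) for f in range(1, 11)]
        pred = [obs(f, 101 if f <= 5 else 102, 2.0 * f, 50) for f in range(1, 11)]
        s = clear_mot(gt, pred)
        assert s.idsw == 1
        assert s.mota == pytest.approx(0.9)
        # identity metrics forced by the split: IDTP=5, IDFP=5, IDFN=5
        assert (s.idtp, s.idfp, s.idfn) == (5, 5, 5)
        assert s.idf1 == pytest.approx(0.5)

    def test_mutual_identity_swap(self):
        # two parallel objects whose predicted ids swap halfway: 2 IDSW
        gt = [obs(f, k, 2.0 * f, 40 * k) for f in range(1, 11) for k in (1, 2)]
        pred = [
            obs(f, (k if f <= 5 else 3 - k) + 10, 2.0 * f, 40 * k)
            for f in range(1, 11)
            for k in (1, 2)
        ]
        s = clear_mot(gt, pred)
        assert s.idsw == 2
        assert s.mota == pytest.approx(1 - 2 / 20)
        assert s.idf1 == pytest.approx(0.5)

    def test_carry_over_prefers_existing_correspondence(self):
        # at frame 2 a new prediction overlaps gt better, but the old
        # correspondence still clears the threshold and is kept: the
        # newcomer is a plain FP and no switch is charged
        gt = [obs(1, 1, 0, 0), obs(2, 1, 0, 0)]
        pred = [obs(1, 5, 1, 0), obs(2, 5, 1, 0), obs(2, 6, 0, 0)]
        s = clear_mot(gt, pred)
        assert (s.fn, s.fp, s.idsw) == (0, 1, 0)

    def test_switch_counted_across_gap(self):
        # object occluded for 3 frames, then found under a new identity
        gt = [obs(f, 1, 2.0 * f, 50) for f in range(1, 11)]
        pred = [obs(f, 101, 2.0 * f, 50) for f in range(1, 4)] + [
            obs(f, 102, 2.0 * f, 50) for f in range(7, 11)
        ]
        s = clear_mot(gt, pred)
        assert s.idsw == 1

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            clear_mot([], [obs(1, 1, 0, 0)])

    def test_duplicate_observation_rejected(self):
        with pytest.raises(ValueError):
            clear_mot([obs(1, 1, 0, 0), obs(1, 1, 5, 5)], [obs(1, 1, 0, 0)])


def brute_force_idtp(gt, pred, thr=0.5):
    """Max total matched frames over all gt↔pred trajectory bijections."""
    gtraj, ptraj = {}, {}
    for o in gt:
        gtraj.setdefault(o.track_id, {})[o.frame] = o
    for o in pred:
        ptraj.setdefault(o.track_id, {})[o.frame] = o

    def m(g, p):
        return sum(
            1
            for f, go in gtraj[g].items()
            if f in ptraj[p] and iou(go.bbox, ptraj[p][f].bbox) >= thr
        )

    gids, pids = sorted(gtraj), sorted(ptraj)
    best = 0
    for k in range(min(len(gids), len(pids)) + 1):
        for gs in itertools.combinations(gids, k):
            for ps in itertools.permutations(pids, k):
                best = max(best, sum(m(g, p) for g, p in zip(gs, ps)))
    return best


def test_idf1_matches_bijection_enumeration_oracle():
    """IDF1 equals brute-force enumeration on 25 random small scenes."""
    rng = np.random.default_rng(5)
    checked = 0
    while checked < 25:
        gt, pred = [], []
        for g in range(rng.integers(1, 5)):
            for f in range(1, rng.integers(5, 31)):
                if rng.random() < 0.8:
                    gt.append(obs(f, g + 1, 10.0 * rng.integers(0, 8), 10.0 * rng.integers(0, 8)))
        for p in range(rng.integers(1, 5)):
            for f in range(1, rng.integers(5, 31)):
                if rng.random() < 0.8:
                    pred.append(obs(f, p + 1, 10.0 * rng.integers(0, 8), 10.0 * rng.integers(0, 8)))
        if not gt or not pred:
            continue
        s = idf1(gt, pred)
        idtp = brute_force_idtp(gt, pred)
        expected = 2 * idtp / (len(gt) + len(pred))
        assert s.idtp == idtp
        assert s.idf1 == pytest.approx(expected)
        checked += 1


def test_mot_metrics_invariant_under_id_relabeling():
    gt, dets = linear_scene(3, 30)
    pred = [obs(o.frame, o.track_id, o.bbox.left, o.bbox.top, o.bbox.width, o.bbox.height)
            for o in gt]
    relabeled = [
        TrackObservation(o.frame, o.track_id * 13 + 5, o.bbox) for o in pred
    ]
    a, b = clear_mot(gt, pred), clear_mot(gt, relabeled)
    assert (a.mota, a.idf1, a.idsw) == (b.mota, b.idf1, b.idsw)


class TestCountPrf:
    def test_direct_tallies(self):
        gt = [CountEvent(f, i, Direction.IN) for i, f in enumerate((10, 50, 90))]
        pred = [CountEvent(f, 10 + i, Direction.IN) for i, f in enumerate((12, 47, 95))]
        pred.append(CountEvent(200, 99, Direction.IN))  # spurious
        res = count_prf(gt, pred, tolerance=15)
        s = res[Direction.IN]
        assert (s.tp, s.fp, s.fn) == (3, 1, 0)
        assert s.precision == pytest.approx(75.0)
        assert s.recall == pytest.approx(100.0)

    def test_tolerance_gates_matching(self):
        gt = [CountEvent(10, 1, Direction.OUT)]
        pred = [CountEvent(40, 2, Direction.OUT)]
        res = count_prf(gt, pred, tolerance=15)
        assert (res[Direction.OUT].tp, res[Direction.OUT].fp, res[Direction.OUT].fn) == (0, 1, 1)
        res = count_prf(gt, pred, tolerance=30)
        assert res[Direction.OUT].tp == 1

    def test_swapping_gt_and_pred_swaps_precision_recall(self):
        rng = np.random.default_rng(9)
        gt = [CountEvent(int(f), i, Direction.IN) for i, f in enumerate(rng.integers(1, 500, 12))]
        pred = [CountEvent(int(f), i, Direction.IN) for i, f in enumerate(rng.integers(1, 500, 9))]
        a = count_prf(gt, pred, 15)[Direction.IN]
        b = count_prf(pred, gt, 15)[Direction.IN]
        assert a.precision == pytest.approx(b.recall)
        assert a.recall == pytest.approx(b.precision)

    def test_retracted_events_do_not_count(self):
        pred = [
            CountEvent(10, 1, Direction.IN),
            CountEvent(20, 1, Direction.IN, correction=True),
        ]
        res = count_prf([CountEvent(12, 5, Direction.IN)], pred, 15)
        assert (res[Direction.IN].tp, res[Direction.IN].fp, res[Direction.IN].fn) == (0, 0, 1)

    def test_undefined_ratios_are_nan(self):
        res = count_prf([], [], 15)
        assert math.isnan(res[Direction.IN].precision)
        assert math.isnan(res[Direction.IN].recall)


class TestF1Score:
    def test_harmonic_mean_fixed_point(self):
        assert f1_score(64.0, 64.0) == pytest.approx(64.0)

    def test_printed_pair(self):
        # the harmonic mean of 69.15% precision and 79.07% recall
        assert f1_score(69.15, 79.07) == pytest.approx(73.78, abs=0.005)

    def test_zero_denominator(self):
        assert math.isnan(f1_score(0.0, 0.0))


class TestBrightness:
    def test_extremes_and_mean(self):
        assert average_brightness(np.zeros((4, 4), dtype=np.uint8)) == 0.0
        assert average_brightness(np.full((4, 4), 255, dtype=np.uint8)) == 255.0
        half = np.zeros((2, 4), dtype=np.uint8)
        half[1] = 255
        assert average_brightness(half) == pytest.approx(127.5)

    def test_rgb_uses_bt601_luma(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., 0] = 255  # pure red
        assert average_brightness(img) == pytest.approx(0.299 * 255)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_brightness(np.zeros((0, 4)))
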