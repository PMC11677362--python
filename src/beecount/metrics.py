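"""Tracking and counting evaluation metrics.

Three layers of evaluation are implemented:

* CLEAR-MOT accuracy: ``MOTA = 1 − (FN + FP + IDSW) / GT``, accumulated
  with the standard frame-by-frame correspondence that prefers carrying
  over the previous frame's matches before Hungarian re-matching.
* Identity metrics: ``IDF1 = IDTP / (IDTP + IDFP/2 + IDFN/2)`` under
  the optimal global bijection between ground-truth and predicted
  trajectories (minimizing IDFP + IDFN).
* Event-level counting precision / recall / F1, computed separately for
  the incoming and the outgoing direction after matching predicted to
  ground-truth events one-to-one within a frame tolerance.

An average-brightness helper supports using image brightness as a
surrogate for scene light intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .counting import CountEvent, net_events
from .geometry import Direction
from .tracker import TrackObservation, iou

_BIG = 1e9


@dataclass
class MotSummary:
    """CLEAR-MOT and identity-metric tallies for one evaluation run."""

    gt_total: int
    fn: int
    fp: int
    idsw: int
    idtp: int
    idfp: int
    idfn: int
    mota: float
    idf1: float

    def summary(self) -> str:
        rows = [
            ("GT boxes", self.gt_total),
            ("FN", self.fn),
            ("FP", self.fp),
            ("IDSW", self.idsw),
            ("IDTP", self.idtp),
            ("IDFP", self.idfp),
            ("IDFN", self.idfn),
            ("MOTA", f"{self.mota:.4f}"),
            ("IDF1", f"{self.idf1:.4f}"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


@dataclass
class CountEvalSummary:
    """Event-level counting tallies for one direction (percent scores)."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def _frames_index(obs: list[TrackObservation]) -> dict[int, dict[int, TrackObservation]]:
    by_frame: dict[int, dict[int, TrackObservation]] = {}
    for o in obs:
        d = by_frame.setdefault(o.frame, {})
        if o.track_id in d:
            raise ValueError(f"duplicate observation for frame {o.frame}, id {o.track_id}")
        d[o.track_id] = o
    return by_frame


def _id_metrics(
    gt: list[TrackObservation], pred: list[TrackObservation], iou_threshold: float
) -> tuple[int, int, int]:
    """(IDTP, IDFP, IDFN) under the optimal trajectory bijection."""
    gt_traj: dict[int, dict[int, TrackObservation]] = {}
    for o in gt:
        gt_traj.setdefault(o.track_id, {})[o.frame] = o
    pr_traj: dict[int, dict[int, TrackObservation]] = {}
    for o in pred:
        pr_traj.setdefault(o.track_id, {})[o.frame] = o
    gids = sorted(gt_traj)
    pids = sorted(pr_traj)
    ng, npr = len(gids), len(pids)
    # overlap[i][j]: frames where gt trajectory i and pred trajectory j match
    overlap = np.zeros((ng, npr))
    for i, g in enumerate(gids):
        for j, p in enumerate(pids):
            m = 0
            for f, go in gt_traj[g].items():
                po = pr_traj[p].get(f)
                if po is not None and iou(go.bbox, po.bbox) >= iou_threshold:
                    m += 1
            overlap[i, j] = m
    len_g = np.array([len(gt_traj[g]) for g in gids])
    len_p = np.array([len(pr_traj[p]) for p in pids])
    # square cost matrix with dummy rows/columns for unmatched trajectories
    n = ng + npr
    cost = np.full((n, n), 0.0)
    cost[:ng, :npr] = len_g[:, None] + len_p[None, :] - 2 * overlap
    cost[:ng, npr:] = _BIG
    cost[np.arange(ng), npr + np.arange(ng)] = len_g  # gt left unmatched
    cost[ng:, :npr] = _BIG
    cost[ng + np.arange(npr), np.arange(npr)] = len_p  # pred left unmatched
    rows, cols = linear_sum_assignment(cost)
    idtp = int(
        sum(overlap[r, c] for r, c in zip(rows, cols) if r < ng and c < npr)
    )
    idfn = int(len_g.sum()) - idtp
    idfp = int(len_p.sum()) - idtp
    return idtp, idfp, idfn


def clear_mot(
    gt: list[TrackObservation],
    pred: list[TrackObservation],
    iou_threshold: float = 0.5,
) -> MotSummary:
    """Full MOT evaluation: CLEAR-MOT tallies plus identity metrics.

    Per frame, correspondences from the previous frame are kept while
    the pair still overlaps at or above ``iou_threshold``; the remaining
    boxes are matched by the Hungarian algorithm maximizing IoU.  An
    identity switch is charged whenever a matched ground-truth object is
    assigned a different predicted identity than at its last match,
    including after occlusion gaps.
    """
    if not gt:
        raise ValueError("MOTA is undefined for empty ground truth")
    gt_frames = _frames_index(gt)
    pr_frames = _frames_index(pred)
    fn = fp = idsw = 0
    corr: dict[int, int] = {}  # gt id -> pred id, current correspondence
    last_match: dict[int, int] = {}  # gt id -> pred id at last match ever
    for f in sorted(set(gt_frames) | set(pr_frames)):
        g = gt_frames.get(f, {})
        p = pr_frames.get(f, {})
        matches: dict[int, int] = {}
        # carry over surviving correspondences
        for gid, pid in corr.items():
            if gid in g and pid in p and iou(g[gid].bbox, p[pid].bbox) >= iou_threshold:
                matches[gid] = pid
        rem_g = [gid for gid in sorted(g) if gid not in matches]
        used_p = set(matches.values())
        rem_p = [pid for pid in sorted(p) if pid not in used_p]
        if rem_g and rem_p:
            mat = np.array(
                [[iou(g[gid].bbox, p[pid].bbox) for pid in rem_p] for gid in rem_g]
            )
            cost = 1.0 - mat
            cost[mat < iou_threshold] = _BIG
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if mat[r, c] >= iou_threshold:
                    matches[rem_g[r]] = rem_p[c]
        for gid, pid in matches.items():
            if gid in last_match and last_match[gid] != pid:
                idsw += 1
            last_match[gid] = pid
        fn += len(g) - len(matches)
        fp += len(p) - len(matches)
        corr = matches
    gt_total = len(gt)
    idtp, idfp, idfn = _id_metrics(gt, pred, iou_threshold)
    mota = 1.0 - (fn + fp + idsw) / gt_total
    denom = idtp + idfp / 2.0 + idfn / 2.0
    idf1_val = idtp / denom if denom > 0 else math.nan
    return MotSummary(gt_total, fn, fp, idsw, idtp, idfp, idfn, mota, idf1_val)


def idf1(
    gt: list[TrackObservation],
    pred: list[TrackObservation],
    iou_threshold: float = 0.5,
) -> MotSummary:
    """Identity metrics (IDTP/IDFP/IDFN/IDF1); returns the full summary."""
    return clear_mot(gt, pred, iou_threshold)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision + recall == 0:
        return math.nan
    return 2.0 * precision * recall / (precision + recall)


def _match_events(
    gt_frames: list[int], pred_frames: list[int], tolerance: int
) -> int:
    """Number of one-to-one |Δframe| ≤ tolerance matches (maximized)."""
    if not gt_frames or not pred_frames:
        return 0
    delta = np.abs(
        np.asarray(gt_frames, dtype=float)[:, None]
        - np.asarray(pred_frames, dtype=float)[None, :]
    )
    cost = delta.copy()
    cost[delta > tolerance] = _BIG
    rows, cols = linear_sum_assignment(cost)
    return int(sum(delta[r, c] <= tolerance for r, c in zip(rows, cols)))


def count_prf(
    gt_events: list[CountEvent],
    pred_events: list[CountEvent],
    tolerance: int = 15,
) -> dict[Direction, CountEvalSummary]:
    """Counting precision/recall/F1 per direction with a frame tolerance.

    Retraction records in either log are applied first (a retracted
    inward event does not count as a predicted event).  Within each
    direction, predicted events are matched one-to-one to ground-truth
    events by minimizing total frame distance, subject to
    ``|Δframe| ≤ tolerance``.  Scores are percentages; undefined ratios
    (zero denominator) are reported as NaN.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    gt_net = net_events(gt_events)
    pred_net = net_events(pred_events)
    out: dict[Direction, CountEvalSummary] = {}
    for direction in (Direction.IN, Direction.OUT):
        gtf = sorted(e.frame for e in gt_net if e.direction == direction)
        prf = sorted(e.frame for e in pred_net if e.direction == direction)
        tp = _match_events(gtf, prf, tolerance)
        fp = len(prf) - tp
        fn = len(gtf) - tp
        precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else math.nan
        recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else math.nan
        out[direction] = CountEvalSummary(
            tp, fp, fn, precision, recall, f1_score(precision, recall)
        )
    return out


def average_brightness(image: np.ndarray) -> float:
    """Mean 8-bit pixel brightness of an image, in [0, 255].

    Color images are converted to grayscale with the ITU-R BT.601 luma
    weights before averaging.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            arr = arr[:, :, 0]
        else:
            arr = arr[:, :, 0] * 0.299 + arr[:, :, 1] * 0.587 + arr[:, :, 2] * 0.114
    elif arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale or 3-channel image")
    return float(arr.mean())
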