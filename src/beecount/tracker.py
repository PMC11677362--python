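"""SORT-style detection-based multi-object tracking.

Per-frame detections are linked into identities with the classic SORT
loop: each live track's bounding box is propagated one frame ahead by a
constant-velocity Kalman filter, the predicted boxes are matched to the
frame's detections by the Hungarian algorithm on an IoU cost matrix
(pairs below ``iou_min`` are inadmissible), matched tracks receive a
Kalman measurement update, unmatched detections spawn new tracks, and
tracks unmatched for more than ``max_age`` frames are terminated.  A new
track only emits output once it has been matched on ``min_hits``
consecutive frames; identities are never reused.

The Kalman state is the standard SORT 7-vector
``[cx, cy, s, r, vx, vy, vs]`` — box center, area ``s = w·h``, aspect
ratio ``r = w/h`` (held constant) and the velocities of the first three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass(frozen=True)
class BBox:
    """Axis-aligned bounding box in pixels (left/top corner + size)."""

    left: float
    top: float
    width: float
    height: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("bounding box must have positive width and height")

    @property
    def center(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class Detection:
    frame: int
    bbox: BBox

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError("frames are 1-based")


@dataclass(frozen=True)
class TrackObservation:
    """One identity-labeled box emitted by the tracker (or ground truth)."""

    frame: int
    track_id: int
    bbox: BBox


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.left + a.width, b.left + b.width) - max(a.left, b.left)
    iy = min(a.top + a.height, b.top + b.height) - max(a.top, b.top)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _bbox_to_z(b: BBox) -> np.ndarray:
    cx, cy = b.center
    return np.array([cx, cy, b.area, b.width / b.height], dtype=float)


def _x_to_bbox(x: np.ndarray, confidence: float = 1.0) -> BBox:
    s = max(x[2], 1e-6)
    r = max(x[3], 1e-6)
    w = np.sqrt(s * r)
    h = s / w
    return BBox(x[0] - w / 2.0, x[1] - h / 2.0, w, h, confidence)


# Constant-velocity model matrices shared by all tracks.
_F = np.eye(7)
_F[0, 4] = _F[1, 5] = _F[2, 6] = 1.0
_H = np.zeros((4, 7))
_H[:4, :4] = np.eye(4)
# Noise settings follow the reference SORT implementation.
_R = np.diag([1.0, 1.0, 10.0, 10.0])
_P0 = np.diag([10.0, 10.0, 10.0, 10.0, 1e4, 1e4, 1e4])
_Q = np.diag([1.0, 1.0, 1.0, 1.0, 0.01, 0.01, 1e-4])


class TrackState:
    """One live track: Kalman state plus lifecycle bookkeeping."""

    def __init__(self, track_id: int, bbox: BBox):
        self.track_id = track_id
        self.x = np.zeros(7)
        self.x[:4] = _bbox_to_z(bbox)
        self.P = _P0.copy()
        self.time_since_update = 0
        self.hit_streak = 1
        self.age = 0
        self.confidence = bbox.confidence

    def predict(self) -> BBox:
        """Constant-velocity time update; returns the predicted box."""
        if self.x[2] + self.x[6] <= 0:  # area would go negative
            self.x[6] = 0.0
        self.x = _F @ self.x
        self.P = _F @ self.P @ _F.T + _Q
        self.age += 1
        if self.time_since_update > 0:
            self.hit_streak = 0
        self.time_since_update += 1
        return _x_to_bbox(self.x, self.confidence)

    def update(self, bbox: BBox) -> None:
        """Kalman measurement update with a matched detection."""
        z = _bbox_to_z(bbox)
        y = z - _H @ self.x
        S = _H @ self.P @ _H.T + _R
        K = self.P @ _H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(7) - K @ _H) @ self.P
        self.time_since_update = 0
        self.hit_streak += 1
        self.confidence = bbox.confidence

    @property
    def bbox(self) -> BBox:
        return _x_to_bbox(self.x, self.confidence)


def associate(
    predicted: list[BBox], detections: list[BBox], iou_min: float = 0.3
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Match predicted track boxes to detections, maximizing total IoU.

    Returns ``(matches, unmatched_track_idx, unmatched_det_idx)`` where
    matches are ``(track_index, detection_index)`` pairs.  Pairs with
    IoU below ``iou_min`` are masked out before solving the assignment,
    so the gate cannot be bypassed by global optimality.
    """
    if not (0 <= iou_min <= 1):
        raise ValueError("iou_min must lie in [0, 1]")
    if not predicted or not detections:
        return [], list(range(len(predicted))), list(range(len(detections)))
    iou_mat = np.array([[iou(p, d) for d in detections] for p in predicted])
    # gated pairs contribute exactly nothing, as if left unmatched, so the
    # solver maximizes total IoU over admissible pairs only
    gain = np.where(iou_mat >= iou_min, iou_mat, 0.0)
    rows, cols = linear_sum_assignment(-gain)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if iou_mat[r, c] >= iou_min]
    matched_r = {r for r, _ in matches}
    matched_c = {c for _, c in matches}
    unmatched_tracks = [i for i in range(len(predicted)) if i not in matched_r]
    unmatched_dets = [j for j in range(len(detections)) if j not in matched_c]
    return matches, unmatched_tracks, unmatched_dets


class SortTracker:
    """Online SORT tracker; feed frames in increasing order via :meth:`step`."""

    def __init__(self, iou_min: float = 0.3, max_age: int = 1, min_hits: int = 3):
        self.iou_min = iou_min
        self.max_age = max_age
        self.min_hits = min_hits
        self.tracks: list[TrackState] = []
        self._next_id = 1
        self._last_frame = 0

    def step(self, frame: int, detections: list[BBox]) -> list[TrackObservation]:
        """Process one frame of detections; returns confirmed observations."""
        if frame <= self._last_frame:
            raise ValueError("frames must be presented in increasing order")
        self._last_frame = frame
        predicted = [t.predict() for t in self.tracks]
        matches, _, unmatched_dets = associate(predicted, detections, self.iou_min)
        for ti, di in matches:
            self.tracks[ti].update(detections[di])
        for di in unmatched_dets:
            self.tracks.append(TrackState(self._next_id, detections[di]))
            self._next_id += 1
        out = [
            TrackObservation(frame, t.track_id, t.bbox)
            for t in self.tracks
            if t.time_since_update == 0 and t.hit_streak >= self.min_hits
        ]
        self.tracks = [t for t in self.tracks if t.time_since_update <= self.max_age]
        return sorted(out, key=lambda o: o.track_id)


def track(
    detections: list[Detection],
    iou_min: float = 0.3,
    max_age: int = 1,
    min_hits: int = 3,
) -> list[TrackObservation]:
    """Run SORT over a full detection list, stepping every frame in range."""
    if not detections:
        return []
    by_frame: dict[int, list[BBox]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d.bbox)
    tracker = SortTracker(iou_min=iou_min, max_age=max_age, min_hits=min_hits)
    out: list[TrackObservation] = []
    for f in range(min(by_frame), max(by_frame) + 1):
        out.extend(tracker.step(f, by_frame.get(f, [])))
    return out
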