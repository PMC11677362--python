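"""Synthetic hive-entrance activity scenes with exact ground truth.

The simulator emulates the behavior classes seen at a monitored hive
entrance — bees flying in from the arena and disappearing into the
entrance, bees emerging and flying away, bees that dip through the
counting region without entering, and bees crawling in the strip
between the entrance and the detection line — and the corruption modes
a real detector-plus-tracker pipeline produces: localization noise,
missed detections, spurious detections and identity switches.

Each trajectory draws all of its randomness from its own counter-keyed
substream of the scenario seed, so adding one trajectory to a scenario
never perturbs the others, and an identical configuration reproduces
the scene bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .counting import CountEvent
from .geometry import Direction, EntranceGeometry, Point2D, hive_direction
from .tracker import BBox, Detection, TrackObservation

BEHAVIORS = ("incoming", "outgoing", "pass_through", "crawler_below_line")


def _default_entrance() -> EntranceGeometry:
    return EntranceGeometry(
        entrance_a=Point2D(280.0, 460.0),
        entrance_b=Point2D(360.0, 460.0),
        body_length_px=30.0,
        image_width=640.0,
        image_height=480.0,
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Scene composition, motion statistics and corruption levels.

    Speeds are pixels per frame; all probabilities are per observation
    (``p_miss``), per frame (``p_idsw``, per track) or per frame
    expected counts (``false_positive_rate``).  ``distance`` is the
    detection-line offset in bee body lengths and also fixes where the
    crawler strip and pass-through dip sit.
    """

    entrance: EntranceGeometry = field(default_factory=_default_entrance)
    frame_rate: float = 25.0
    duration: int = 400
    n_incoming: int = 5
    n_outgoing: int = 5
    n_pass_through: int = 0
    n_crawler: int = 0
    speed_mean: float = 4.5
    speed_sd: float = 1.0
    motion_jitter_sigma: float = 0.8
    detection_noise_sigma: float = 1.0
    p_miss: float = 0.05
    false_positive_rate: float = 0.1
    p_idsw: float = 0.0
    distance: float = 0.5
    pass_depth_frac: float = 0.5
    serialized: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_miss", "p_idsw"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_incoming", "n_outgoing", "n_pass_through", "n_crawler"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration < 1 or self.false_positive_rate < 0:
            raise ValueError("invalid duration or false_positive_rate")


@dataclass
class GroundTruth:
    """True tracks, true counting events and per-identity behavior labels."""

    tracks: list[TrackObservation]
    events: list[CountEvent]
    behaviors: dict[int, str]


class Scene(NamedTuple):
    ground_truth: GroundTruth
    detections: list[Detection]
    corrupted_tracks: list[TrackObservation]


def _entrance_frame(geom: EntranceGeometry):
    """(lerp, tangent, hive-normal) helpers for entrance-relative coords."""
    a, b = geom.entrance_a, geom.entrance_b
    h = hive_direction(geom)
    tx, ty = b.x - a.x, b.y - a.y
    norm = math.hypot(tx, ty)

    def at(u: float, depth: float) -> np.ndarray:
        """Point at fraction ``u`` along the entrance, ``depth`` px into the arena."""
        return np.array(
            [a.x + u * tx - h.x * depth, a.y + u * ty - h.y * depth]
        )

    return at, (tx / norm, ty / norm), h


def _clip(pt: np.ndarray, geom: EntranceGeometry) -> np.ndarray:
    return np.array(
        [
            min(max(pt[0], 2.0), geom.image_width - 2.0),
            min(max(pt[1], 2.0), geom.image_height - 2.0),
        ]
    )


def _sample_polyline(
    waypoints: list[np.ndarray],
    speed: float,
    jitter_sigma: float,
    rng: np.random.Generator,
    jitter_last: bool = True,
    jitter_axis: tuple[float, float] | None = None,
) -> list[np.ndarray]:
    """Walk the polyline at ``speed`` px/frame with per-frame Gaussian jitter.

    ``jitter_axis`` restricts the jitter to one direction (used for the
    crawler so it cannot wander across the detection line).
    """
    pts = [np.asarray(w, dtype=float) for w in waypoints]
    seglen = [np.linalg.norm(pts[i + 1] - pts[i]) for i in range(len(pts) - 1)]
    total = sum(seglen)
    n = max(4, int(math.ceil(total / speed)) + 1)
    distances = np.linspace(0.0, total, n)
    centers = []
    for d in distances:
        acc = 0.0
        pos = pts[-1]
        for i, sl in enumerate(seglen):
            if d <= acc + sl or i == len(seglen) - 1:
                t = 0.0 if sl == 0 else min(1.0, (d - acc) / sl)
                pos = pts[i] * (1 - t) + pts[i + 1] * t
                break
            acc += sl
        centers.append(pos.copy())
    for i, c in enumerate(centers):
        if not jitter_last and i == len(centers) - 1:
            continue
        if jitter_axis is None:
            c += rng.normal(0.0, jitter_sigma, size=2)
        else:
            c += rng.normal(0.0, jitter_sigma) * np.asarray(jitter_axis)
    return centers


def generate_trajectory(
    behavior: str,
    config: ScenarioConfig,
    rng: np.random.Generator,
    track_id: int = 1,
    start_frame: int = 1,
) -> list[TrackObservation]:
    """One trajectory of the given behavior class as track observations.

    Bounding boxes are axis-aligned, body_length × body_length/2,
    centered on the trajectory points.
    """
    if behavior not in BEHAVIORS:
        raise ValueError(f"unknown behavior {behavior!r}; expected one of {BEHAVIORS}")
    geom = config.entrance
    at, tangent, _ = _entrance_frame(geom)
    L = geom.body_length_px
    offset = config.distance * L
    # per-frame displacement is capped at a quarter body length: any
    # frame-to-frame overlap tracker presumes consecutive boxes of a
    # body-sized object intersect, which bounds apparent speed at the
    # camera's frame rate
    speed = float(np.clip(rng.normal(config.speed_mean, config.speed_sd), 1.5, 0.25 * L))
    jitter_axis = None
    jitter_last = True

    if behavior in ("incoming", "outgoing"):
        hive_end = at(rng.uniform(0.15, 0.85), 2.0)
        far = _clip(at(rng.uniform(-0.8, 1.8), rng.uniform(6 * L, 10 * L)), geom)
        mids = []
        a0 = geom.entrance_a
        hx, hy = hive_direction(geom)
        ex, ey = geom.entrance_b.x - a0.x, geom.entrance_b.y - a0.y
        e_len2 = ex * ex + ey * ey
        for t in sorted(rng.uniform(0.3, 0.8, size=rng.integers(1, 3))):
            perp = rng.normal(0.0, 1.5 * L, size=2)
            mid = _clip(far * (1 - t) + hive_end * t + perp, geom)
            # in-flight waypoints stay well above the detection line and
            # laterally over the entrance, so the final approach crosses
            # the line segment exactly once (frontal approach)
            depth = -((mid[0] - a0.x) * hx + (mid[1] - a0.y) * hy)
            u = ((mid[0] - a0.x) * ex + (mid[1] - a0.y) * ey) / e_len2
            mid = at(min(max(u, 0.05), 0.95), max(depth, 1.5 * L))
            mids.append(mid)
        waypoints = [far, *mids, hive_end]
        if behavior == "outgoing":
            waypoints = waypoints[::-1]
        # the entrance-side endpoint is exact so the bee ends (or starts)
        # just inside the counting box, never behind the entrance
        jitter_last = behavior == "outgoing"
        centers = _sample_polyline(
            waypoints, speed, config.motion_jitter_sigma, rng, jitter_last=jitter_last
        )
        if behavior == "outgoing":
            centers[0] = waypoints[0]
        # keep the flight path strictly on the arena side of the
        # entrance: a jittered point behind it would register a spurious
        # bottom-edge crossing
        a = geom.entrance_a
        hx, hy = hive_direction(geom)
        for c in centers:
            depth = -((c[0] - a.x) * hx + (c[1] - a.y) * hy)
            if depth < 1.0:
                c[0] -= (1.0 - depth) * hx
                c[1] -= (1.0 - depth) * hy
    elif behavior == "pass_through":
        u1 = rng.uniform(-0.1, 0.1)
        u2 = rng.uniform(0.9, 1.1)
        if rng.random() < 0.5:
            u1, u2 = u2, u1
        depth = config.pass_depth_frac * offset
        high = rng.uniform(0.8 * L, 1.2 * L)
        um = rng.uniform(0.42, 0.58)
        # a smooth swoop: lateral flight with a Gaussian dip down to
        # ``depth`` over the middle of the entrance — no sharp turns, so
        # a motion-model tracker can follow it
        sigma_u = 0.3
        us = np.linspace(u1, u2, 400)
        ds = high - (high - depth) * np.exp(-(((us - um) / sigma_u) ** 2))
        fine = np.array([at(u, d) for u, d in zip(us, ds)])
        # resample the curve at constant arc length so the per-frame
        # displacement never exceeds the speed cap
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(fine, axis=0), axis=1))]
        )
        n_frames = max(6, int(math.ceil(arc[-1] / speed)) + 1)
        centers = []
        for s in np.linspace(0.0, arc[-1], n_frames):
            i = int(np.searchsorted(arc, s, side="right") - 1)
            i = min(i, len(fine) - 2)
            seg = arc[i + 1] - arc[i]
            t = 0.0 if seg == 0 else (s - arc[i]) / seg
            c = fine[i] * (1 - t) + fine[i + 1] * t
            c = c + rng.normal(0.0, config.motion_jitter_sigma, size=2)
            centers.append(_clip(c, geom))
    else:  # crawler_below_line
        side = -0.45 if rng.random() < 0.5 else 1.45
        exit_side = -0.45 if rng.random() < 0.5 else 1.45
        depths = rng.uniform(0.25 * offset, 0.75 * offset, size=4)
        waypoints = [
            _clip(at(side, depths[0]), geom),
            at(rng.uniform(0.1, 0.45), depths[1]),
            at(rng.uniform(0.55, 0.9), depths[2]),
            _clip(at(exit_side, depths[3]), geom),
        ]
        # crawling is slower and the jitter is tangential only, so the
        # crawler can never wander across the detection line
        speed = max(1.0, speed / 2.0)
        jitter_axis = tangent
        centers = _sample_polyline(
            waypoints, speed, config.motion_jitter_sigma, rng, jitter_axis=jitter_axis
        )

    obs = []
    for i, c in enumerate(centers):
        bbox = BBox(c[0] - L / 2.0, c[1] - L / 4.0, L, L / 2.0)
        obs.append(TrackObservation(start_frame + i, track_id, bbox))
    return obs


def _true_events(behavior: str, obs: list[TrackObservation]) -> list[CountEvent]:
    if behavior == "incoming":
        return [CountEvent(obs[-1].frame, obs[0].track_id, Direction.IN)]
    if behavior == "outgoing":
        return [CountEvent(obs[0].frame, obs[0].track_id, Direction.OUT)]
    return []


def generate_scene(config: ScenarioConfig) -> Scene:
    """Ground truth, corrupted detections and corrupted tracks for one scene."""
    behaviors = (
        ["incoming"] * config.n_incoming
        + ["outgoing"] * config.n_outgoing
        + ["pass_through"] * config.n_pass_through
        + ["crawler_below_line"] * config.n_crawler
    )
    tracks: list[TrackObservation] = []
    events: list[CountEvent] = []
    labels: dict[int, str] = {}
    next_start = 1  # serialized mode: trajectories take turns
    duration = config.duration
    for k, behavior in enumerate(behaviors):
        rng = np.random.default_rng([config.seed, k])
        tid = k + 1
        obs = generate_trajectory(behavior, config, rng, track_id=tid)
        span = len(obs)
        if config.serialized:
            start = next_start
            next_start = start + span + 5
            duration = max(duration, start + span - 1)
        else:
            latest_start = max(1, config.duration - span + 1)
            start = int(rng.integers(1, latest_start + 1))
        obs = [replace(o, frame=o.frame - 1 + start) for o in obs]
        kept = [o for o in obs if o.frame <= duration]
        if not kept:
            continue
        tracks.extend(kept)
        labels[tid] = behavior
        if len(kept) == span:  # truncated trajectories carry no events
            events.extend(_true_events(behavior, kept))
    tracks.sort(key=lambda o: (o.frame, o.track_id))
    events.sort(key=lambda e: e.frame)
    gt = GroundTruth(tracks, events, labels)

    # -- detection-level corruption ------------------------------------
    det_rng = np.random.default_rng([config.seed, 1_000_003])
    detections: list[Detection] = []
    for o in tracks:
        if det_rng.random() < config.p_miss:
            continue
        dx, dy = (
            det_rng.normal(0.0, config.detection_noise_sigma, size=2)
            if config.detection_noise_sigma > 0
            else (0.0, 0.0)
        )
        b = o.bbox
        detections.append(
            Detection(o.frame, BBox(b.left + dx, b.top + dy, b.width, b.height, 1.0))
        )
    geom = config.entrance
    fp_rng = np.random.default_rng([config.seed, 2_000_003])
    if config.false_positive_rate > 0:
        L = geom.body_length_px
        for f in range(1, duration + 1):
            for _ in range(fp_rng.poisson(config.false_positive_rate)):
                w = L * fp_rng.uniform(0.7, 1.3)
                h = L / 2.0 * fp_rng.uniform(0.7, 1.3)
                left = fp_rng.uniform(0, geom.image_width - w)
                top = fp_rng.uniform(0, geom.image_height - h)
                detections.append(Detection(f, BBox(left, top, w, h, 0.5)))
    detections.sort(key=lambda d: (d.frame, d.bbox.left, d.bbox.top))

    # -- track-level identity-switch corruption ------------------------
    sw_rng = np.random.default_rng([config.seed, 3_000_003])
    corrupted: list[TrackObservation] = []
    next_id = len(behaviors) + 1
    by_id: dict[int, list[TrackObservation]] = {}
    for o in tracks:
        by_id.setdefault(o.track_id, []).append(o)
    for tid in sorted(by_id):
        current = tid
        for i, o in enumerate(sorted(by_id[tid], key=lambda o: o.frame)):
            if i > 0 and sw_rng.random() < config.p_idsw:
                current = next_id
                next_id += 1
            corrupted.append(replace(o, track_id=current))
    corrupted.sort(key=lambda o: (o.frame, o.track_id))
    return Scene(gt, detections, corrupted)


def diurnal_rates(hour: int, peak_rate: float, base_rate: float = 0.0) -> float:
    """Expected entrance events per hour at the given hour of day.

    A cosine bump over the daylight hours (06–18 h) rises from
    ``base_rate`` at dawn/dusk to ``peak_rate`` at noon; outside
    daylight the rate stays at ``base_rate``, mimicking the circadian
    activity rhythm of a foraging colony.
    """
    if not 0 <= hour <= 23:
        raise ValueError("hour must be in 0..23")
    if not peak_rate >= base_rate >= 0:
        raise ValueError("need peak_rate >= base_rate >= 0")
    if abs(hour - 12) > 6:
        return base_rate
    return base_rate + (peak_rate - base_rate) * math.cos(math.pi * (hour - 12) / 12.0)
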