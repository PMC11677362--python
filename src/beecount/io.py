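"""MOTChallenge text I/O, event CSVs, run configuration and the pipeline.

The interchange format is the 10-field comma-separated MOTChallenge
dialect::

    frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z

Raw detections carry ``id = -1``.  Ground-truth files that use field 7
as a validity flag and fields 8–9 as class/visibility are accepted and
normalized; files with only 9 fields are accepted too.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .counting import CountEvent, CountResult, box_count, net_events, single_line_count
from .geometry import Direction, EntranceGeometry, Point2D, build_box, build_single_line
from .tracker import BBox, Detection, TrackObservation, track

log = logging.getLogger("beecount")


@dataclass
class RunConfig:
    """Pipeline configuration; the defaults reproduce the selected setup:
    box method with the top line at half a bee body length."""

    entrance_a: tuple[float, float] = (280.0, 460.0)
    entrance_b: tuple[float, float] = (360.0, 460.0)
    body_length_px: float = 30.0
    image_width: float = 640.0
    image_height: float = 480.0
    method: str = "box"
    distance: float = 0.5
    bottom_margin_px: float = 0.0
    iou_min: float = 0.3
    max_age: int = 1
    min_hits: int = 3
    eval_iou: float = 0.5
    tolerance: int = 15
    purge_after: int | None = None

    def geometry(self) -> EntranceGeometry:
        return EntranceGeometry(
            Point2D(*self.entrance_a),
            Point2D(*self.entrance_b),
            self.body_length_px,
            self.image_width,
            self.image_height,
        )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a key-value YAML config file; keyword overrides win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of configuration keys")
    known = RunConfig.__dataclass_fields__
    for key in data:
        if key not in known:
            raise ValueError(f"{path}: unknown configuration key {key!r}")
    data.update(overrides)
    for key in ("entrance_a", "entrance_b"):
        if key in data:
            data[key] = tuple(float(v) for v in data[key])
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_mot(path: str | Path) -> list[Detection | TrackObservation]:
    """Parse a MOTChallenge text file.

    Lines with ``id == -1`` become :class:`Detection`; all others become
    :class:`TrackObservation`.  Records are returned sorted by
    ``(frame, id)``.  A malformed line raises with its line number.
    """
    records: list[tuple[int, int, Detection | TrackObservation]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 7 comma-separated fields, got {len(parts)}"
                )
            try:
                frame = int(float(parts[0]))
                tid = int(float(parts[1]))
                left, top, width, height = (float(v) for v in parts[2:6])
                conf = float(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from None
            bbox = BBox(left, top, width, height, min(max(conf, 0.0), 1.0))
            if tid == -1:
                records.append((frame, tid, Detection(frame, bbox)))
            else:
                records.append((frame, tid, TrackObservation(frame, tid, bbox)))
    if not records:
        warnings.warn(f"{path}: empty MOT file", stacklevel=2)
    records.sort(key=lambda r: (r[0], r[1]))
    return [r[2] for r in records]


def read_detections(path: str | Path) -> list[Detection]:
    out = []
    for r in read_mot(path):
        if isinstance(r, TrackObservation):
            r = Detection(r.frame, r.bbox)
        out.append(r)
    return out


def read_tracks(path: str | Path) -> list[TrackObservation]:
    out = []
    for r in read_mot(path):
        if isinstance(r, Detection):
            raise ValueError(f"{path}: contains id=-1 detection records, not tracks")
        out.append(r)
    return out


def write_mot(
    items: list[Detection | TrackObservation], path: str | Path, gt: bool = False
) -> None:
    """Write records in the 10-field dialect with 2-decimal boxes.

    With ``gt=True`` the trailing fields follow the ground-truth
    convention (validity flag 1, class 1, full visibility).
    """
    with open(path, "w") as fh:
        for item in items:
            tid = -1 if isinstance(item, Detection) else item.track_id
            b = item.bbox
            if gt:
                tail = "1,1,1.0"
            else:
                tail = f"{b.confidence:.2f},-1,-1,-1"
            fh.write(
                f"{item.frame},{tid},{b.left:.2f},{b.top:.2f},"
                f"{b.width:.2f},{b.height:.2f},{tail}\n"
            )


def write_events(events: list[CountEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "track_id", "direction", "line_label", "correction"])
        for e in events:
            w.writerow([e.frame, e.track_id, e.direction.value, e.line_label, int(e.correction)])


def read_events(path: str | Path) -> list[CountEvent]:
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            events.append(
                CountEvent(
                    int(row["frame"]),
                    int(row["track_id"]),
                    Direction(row["direction"]),
                    row.get("line_label", "single"),
                    bool(int(row.get("correction", 0))),
                )
            )
    return events


def run_pipeline(
    detections: list[Detection], config: RunConfig
) -> tuple[list[TrackObservation], CountResult]:
    """Detections → SORT tracking → crossing counting."""
    log.info("pipeline: tracking %d detections", len(detections))
    tracks = track(
        detections,
        iou_min=config.iou_min,
        max_age=config.max_age,
        min_hits=config.min_hits,
    )
    log.info("pipeline: counting over %d track observations", len(tracks))
    geom = config.geometry()
    if config.method == "line":
        result = single_line_count(tracks, build_single_line(geom, config.distance))
    elif config.method == "box":
        result = box_count(
            tracks,
            build_box(geom, config.distance, config.bottom_margin_px),
            purge_after=config.purge_after,
        )
    else:
        raise ValueError(f"unknown counting method {config.method!r}")
    log.info("pipeline: in=%d out=%d", result.in_count, result.out_count)
    return tracks, result


def hourly_report(events: list[CountEvent], frame_rate: float) -> pd.DataFrame:
    """Net in/out counts binned into half-open wall-clock hours [h, h+1).

    Frame ``f`` maps to time ``f / frame_rate`` seconds from the start
    of the recording.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    kept = net_events(events)
    if not kept:
        return pd.DataFrame(columns=["hour", "in", "out"]).astype(int)
    frames_per_hour = 3600.0 * frame_rate
    hours = [int(math.floor(e.frame / frames_per_hour)) for e in kept]
    table = {h: [0, 0] for h in range(max(hours) + 1)}
    for e, h in zip(kept, hours):
        table[h][0 if e.direction == Direction.IN else 1] += 1
    return pd.DataFrame(
        {
            "hour": list(table),
            "in": [v[0] for v in table.values()],
            "out": [v[1] for v in table.values()],
        }
    )
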