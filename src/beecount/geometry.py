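"""Directed-segment geometry for virtual-line crossing detection.

A *detection line* is a finite directed segment placed near the hive
entrance.  The direction of the segment encodes which side of it is the
hive ("in") side: a point ``x`` is on the hive side of the line ``p→q``
exactly when the 2-D cross product ``(q − p) × (x − p)`` is positive.
All coordinates are image pixel coordinates (origin top-left, y grows
downward, sub-pixel values allowed).

An in/out event is detected from the movement of a tracked center point
between two consecutive frames: the segment from the previous center M
to the current center N must intersect the finite detection line, and
the side occupied by N decides the direction (hive side → IN).  This is
equivalent in sign to the angle between the movement vector MN and the
line vector PQ, but avoids angle wrap-around.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple


class Point2D(NamedTuple):
    """A point in image pixel coordinates (y increases downward)."""

    x: float
    y: float


class Direction(str, enum.Enum):
    """Outcome of a crossing test."""

    IN = "IN"
    OUT = "OUT"
    NONE = "NONE"


@dataclass(frozen=True)
class DetectionLine:
    """A finite directed detection segment.

    The hive ("in") side is, by convention, the positive side of the
    cross product ``(q − p) × (x − p)``.  The ``build_single_line`` and
    ``build_box`` constructors enforce this convention so the endpoint
    order supplied by a user cannot flip in/out.
    """

    p: Point2D
    q: Point2D
    label: str = "single"  # one of: top, bottom, left, right, single

    def __post_init__(self) -> None:
        if self.p == self.q:
            raise ValueError("degenerate detection line: p == q")


@dataclass(frozen=True)
class EntranceGeometry:
    """Hive-entrance segment, bee body length and image extent.

    ``body_length_px`` is the pixel length of one bee; line and box
    offsets are expressed in multiples of it.
    """

    entrance_a: Point2D
    entrance_b: Point2D
    body_length_px: float
    image_width: float
    image_height: float

    def __post_init__(self) -> None:
        if self.entrance_a == self.entrance_b:
            raise ValueError("entrance segment is degenerate")
        if self.body_length_px <= 0:
            raise ValueError("body_length_px must be positive")
        for pt in (self.entrance_a, self.entrance_b):
            if not (0 <= pt.x <= self.image_width and 0 <= pt.y <= self.image_height):
                raise ValueError(f"entrance endpoint {pt} outside image bounds")


@dataclass(frozen=True)
class CrossingEvent:
    """A single detected line crossing of one track identity.

    ``frame`` is the later of the two consecutive frames involved.
    """

    frame: int
    track_id: int
    line_label: str
    direction: Direction


def cross2d(ax: float, ay: float, bx: float, by: float) -> float:
    return ax * by - ay * bx


def side_of_line(line: DetectionLine, x: Point2D) -> int:
    """Sign of the cross product (q−p) × (x−p): +1 hive side, −1 outside, 0 on the line."""
    c = cross2d(line.q.x - line.p.x, line.q.y - line.p.y, x.x - line.p.x, x.y - line.p.y)
    if c > 0:
        return 1
    if c < 0:
        return -1
    return 0


def _orient(a: Point2D, b: Point2D, c: Point2D) -> int:
    v = cross2d(b.x - a.x, b.y - a.y, c.x - a.x, c.y - a.y)
    if v > 0:
        return 1
    if v < 0:
        return -1
    return 0


def _on_segment(a: Point2D, b: Point2D, c: Point2D) -> bool:
    # c collinear with a-b assumed; is c within the bounding box of a-b?
    return (
        min(a.x, b.x) <= c.x <= max(a.x, b.x)
        and min(a.y, b.y) <= c.y <= max(a.y, b.y)
    )


def segments_intersect(a1: Point2D, a2: Point2D, b1: Point2D, b2: Point2D) -> bool:
    """True iff the closed segments a1a2 and b1b2 share at least one point."""
    d1 = _orient(b1, b2, a1)
    d2 = _orient(b1, b2, a2)
    d3 = _orient(a1, a2, b1)
    d4 = _orient(a1, a2, b2)
    if d1 != d2 and d3 != d4 and d1 != 0 and d2 != 0 and d3 != 0 and d4 != 0:
        return True
    # proper crossing with one endpoint exactly on the other segment,
    # or collinear overlap
    if d1 == 0 and _on_segment(b1, b2, a1):
        return True
    if d2 == 0 and _on_segment(b1, b2, a2):
        return True
    if d3 == 0 and _on_segment(a1, a2, b1):
        return True
    if d4 == 0 and _on_segment(a1, a2, b2):
        return True
    return d1 != d2 and d3 != d4


def _effective_side(s: int) -> int:
    # A point exactly on the line counts as the outside: a bee resting on
    # the line generates exactly one event when it finally leaves it.
    return 1 if s > 0 else -1


def crossing_direction(line: DetectionLine, m: Point2D, n: Point2D) -> Direction:
    """Direction of the crossing of ``line`` by the movement M→N, if any.

    M is the track center at the previous frame, N at the current frame.
    Returns IN when N ends on the hive side, OUT when it ends outside,
    NONE when the movement does not cross the finite segment.
    """
    sm = _effective_side(side_of_line(line, m))
    sn = _effective_side(side_of_line(line, n))
    if sm == sn:
        return Direction.NONE
    if not segments_intersect(m, n, line.p, line.q):
        return Direction.NONE
    return Direction.IN if sn > 0 else Direction.OUT


def hive_direction(geom: EntranceGeometry) -> Point2D:
    """Unit normal of the entrance segment pointing toward the hive.

    The hive is taken to lie on the side of the entrance segment closer
    to the image border (the camera looks at the entrance from inside
    the arena, so the hive occupies the thin margin behind it).
    """
    ex = geom.entrance_b.x - geom.entrance_a.x
    ey = geom.entrance_b.y - geom.entrance_a.y
    norm = math.hypot(ex, ey)
    nx, ny = -ey / norm, ex / norm
    mid = Point2D(
        (geom.entrance_a.x + geom.entrance_b.x) / 2.0,
        (geom.entrance_a.y + geom.entrance_b.y) / 2.0,
    )

    def border_distance(dx: float, dy: float) -> float:
        # travel from mid along (dx, dy) until leaving the image rectangle
        best = math.inf
        if dx > 0:
            best = min(best, (geom.image_width - mid.x) / dx)
        elif dx < 0:
            best = min(best, -mid.x / dx)
        if dy > 0:
            best = min(best, (geom.image_height - mid.y) / dy)
        elif dy < 0:
            best = min(best, -mid.y / dy)
        return best

    if border_distance(nx, ny) <= border_distance(-nx, -ny):
        return Point2D(nx, ny)
    return Point2D(-nx, -ny)


def _directed(a: Point2D, b: Point2D, positive_toward: Point2D, label: str) -> DetectionLine:
    """Detection line through a→b ordered so ``positive_toward`` is on the + side."""
    c = cross2d(b.x - a.x, b.y - a.y, positive_toward.x - a.x, positive_toward.y - a.y)
    if c > 0:
        return DetectionLine(a, b, label)
    if c < 0:
        return DetectionLine(b, a, label)
    raise ValueError("reference point is collinear with the line")


def _check_in_bounds(geom: EntranceGeometry, pt: Point2D, what: str) -> None:
    if not (0 <= pt.x <= geom.image_width and 0 <= pt.y <= geom.image_height):
        raise ValueError(f"{what} endpoint {pt} falls outside the image bounds")


def build_single_line(geom: EntranceGeometry, distance: float) -> DetectionLine:
    """Detection line parallel to the entrance, offset into the arena.

    ``distance`` is in bee body lengths; the line has the same length as
    the entrance segment and is placed ``distance · body_length`` away
    from the hive.  The hive side is the positive side of the returned
    line regardless of the entrance endpoint order.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    h = hive_direction(geom)
    off = distance * geom.body_length_px
    a = Point2D(geom.entrance_a.x - h.x * off, geom.entrance_a.y - h.y * off)
    b = Point2D(geom.entrance_b.x - h.x * off, geom.entrance_b.y - h.y * off)
    _check_in_bounds(geom, a, "detection line")
    _check_in_bounds(geom, b, "detection line")
    mid = Point2D((a.x + b.x) / 2 + h.x, (a.y + b.y) / 2 + h.y)
    return _directed(a, b, mid, "single")


def build_box(
    geom: EntranceGeometry, distance: float, bottom_margin_px: float = 0.0
) -> list[DetectionLine]:
    """Four detection lines forming the counting box around the entrance.

    The top line sits ``distance`` body lengths from the entrance on the
    arena side (exactly where the single-line method would place its
    line); the bottom line sits ``bottom_margin_px`` pixels behind the
    entrance toward the hive (default 0: it coincides with the entrance
    segment); the left/right lines join their endpoints, so their length
    follows the top-line offset.  Every line is directed so the box
    interior is its positive side.  Returned in the fixed processing
    order [top, bottom, left, right].
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if bottom_margin_px < 0:
        raise ValueError("bottom_margin_px must be >= 0")
    if distance * geom.body_length_px + bottom_margin_px <= 0:
        raise ValueError("degenerate box: top and bottom lines coincide")
    h = hive_direction(geom)
    top_off = distance * geom.body_length_px
    ta = Point2D(geom.entrance_a.x - h.x * top_off, geom.entrance_a.y - h.y * top_off)
    tb = Point2D(geom.entrance_b.x - h.x * top_off, geom.entrance_b.y - h.y * top_off)
    ba = Point2D(
        geom.entrance_a.x + h.x * bottom_margin_px, geom.entrance_a.y + h.y * bottom_margin_px
    )
    bb = Point2D(
        geom.entrance_b.x + h.x * bottom_margin_px, geom.entrance_b.y + h.y * bottom_margin_px
    )
    for pt in (ta, tb, ba, bb):
        _check_in_bounds(geom, pt, "box")
    center = Point2D(
        (ta.x + tb.x + ba.x + bb.x) / 4.0, (ta.y + tb.y + ba.y + bb.y) / 4.0
    )
    return [
        _directed(ta, tb, center, "top"),
        _directed(ba, bb, center, "bottom"),
        _directed(ta, ba, center, "left"),
        _directed(tb, bb, center, "right"),
    ]
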