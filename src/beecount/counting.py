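"""In/out counting from identity-labeled tracks crossing virtual lines.

Two counting algorithms are provided:

* **single-line method** — one detection line offset from the hive
  entrance; every signed crossing of the line by a track's center
  increments the in- or out-counter.  A bee that dips across the line
  and returns without entering the hive is counted once in each
  direction — a known error mode of this method.

* **box method** — four detection lines forming a rectangle around the
  entrance, with an *already-counted* queue of identities that have
  entered the box.  When an identity that previously crossed inward
  crosses outward again, its inward count is retracted instead of
  incrementing the out-counter, which cancels pass-through traffic and
  also catches bees arriving or leaving sideways.

Both methods use only the positions of two consecutive observed frames
of each identity, which limits the damage an identity switch can do.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .geometry import DetectionLine, Direction, Point2D, crossing_direction
from .tracker import TrackObservation


@dataclass(frozen=True)
class CountEvent:
    """One counting event; ``correction=True`` marks a pass-through retraction.

    A retraction carries ``direction=IN``: it cancels one previously
    recorded inward crossing of the same identity.
    """

    frame: int
    track_id: int
    direction: Direction
    line_label: str = "single"
    correction: bool = False


@dataclass
class CountResult:
    in_count: int
    out_count: int
    events: list[CountEvent] = field(default_factory=list)


@dataclass
class BoxCounterState:
    """Mutable state of the box counter.

    ``already_counted`` is an order-preserving, duplicate-free queue of
    identities whose inward crossing has been counted but not yet
    cancelled; ``last_center`` maps each identity to its most recent
    observed center point and frame.
    """

    in_count: int = 0
    out_count: int = 0
    already_counted: deque[int] = field(default_factory=deque)
    last_center: dict[int, tuple[Point2D, int]] = field(default_factory=dict)


def replay_events(events: list[CountEvent]) -> tuple[int, int]:
    """Recompute (in_count, out_count) totals from an event log."""
    n_in = 0
    n_out = 0
    for e in events:
        if e.correction:
            n_in -= 1
        elif e.direction == Direction.IN:
            n_in += 1
        elif e.direction == Direction.OUT:
            n_out += 1
    return n_in, n_out


def net_events(events: list[CountEvent]) -> list[CountEvent]:
    """Event log with retractions applied: each correction removes the
    most recent surviving inward event of the same identity."""
    kept: list[CountEvent] = []
    for e in sorted(events, key=lambda e: e.frame):
        if not e.correction:
            kept.append(e)
            continue
        for i in range(len(kept) - 1, -1, -1):
            k = kept[i]
            if k.track_id == e.track_id and k.direction == Direction.IN:
                del kept[i]
                break
    return kept


def _transitions(tracks: list[TrackObservation]):
    """Yield (frame, track_id, m, n) center movements per identity,
    ordered chronologically by the later frame.

    Consecutive *observed* frames are paired: gaps from missed
    detections are bridged by keeping the last observed center as M.
    """
    last: dict[int, tuple[int, Point2D]] = {}
    moves = []
    for obs in sorted(tracks, key=lambda o: (o.frame, o.track_id)):
        c = Point2D(*obs.bbox.center)
        prev = last.get(obs.track_id)
        if prev is not None:
            moves.append((obs.frame, obs.track_id, prev[1], c))
        last[obs.track_id] = (obs.frame, c)
    return moves


def single_line_count(tracks: list[TrackObservation], line: DetectionLine) -> CountResult:
    """Count in/out events as signed crossings of one detection line."""
    result = CountResult(0, 0)
    for frame, tid, m, n in _transitions(tracks):
        d = crossing_direction(line, m, n)
        if d == Direction.IN:
            result.in_count += 1
            result.events.append(CountEvent(frame, tid, Direction.IN, line.label))
        elif d == Direction.OUT:
            result.out_count += 1
            result.events.append(CountEvent(frame, tid, Direction.OUT, line.label))
    return result


def box_count(
    tracks: list[TrackObservation],
    box: list[DetectionLine],
    purge_after: int | None = None,
) -> CountResult:
    """Count in/out events with the box method and pass-through retraction.

    ``box`` is the [top, bottom, left, right] list from
    :func:`~beecount.geometry.build_box`; edges are evaluated in that
    fixed order when one displacement crosses more than one edge.
    Identities unseen for more than ``purge_after`` frames are dropped
    from the already-counted queue (default: never, matching the plain
    algorithm; set it when upstream identities may be reused).
    """
    if len(box) != 4:
        raise ValueError("box must consist of exactly 4 detection lines")
    state = BoxCounterState()
    events: list[CountEvent] = []
    for frame, tid, m, n in _transitions(tracks):
        if purge_after is not None:
            stale = [
                i for i, (_, f) in state.last_center.items() if frame - f > purge_after
            ]
            for i in stale:
                del state.last_center[i]
                if i in state.already_counted:
                    state.already_counted.remove(i)
        for edge in box:
            d = crossing_direction(edge, m, n)
            if d == Direction.IN:
                state.in_count += 1
                events.append(CountEvent(frame, tid, Direction.IN, edge.label))
                if tid not in state.already_counted:
                    state.already_counted.append(tid)
            elif d == Direction.OUT:
                if tid in state.already_counted:
                    state.already_counted.remove(tid)
                    state.in_count -= 1
                    events.append(
                        CountEvent(frame, tid, Direction.IN, edge.label, correction=True)
                    )
                else:
                    state.out_count += 1
                    events.append(CountEvent(frame, tid, Direction.OUT, edge.label))
        state.last_center[tid] = (n, frame)
    return CountResult(state.in_count, state.out_count, events)
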