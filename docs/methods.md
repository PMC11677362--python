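# Methods

This note documents the models, conventions and design choices behind
`beecount`, in the order data flows through the pipeline: geometry →
tracking → counting → evaluation → simulation.

## Crossing geometry

All coordinates are image pixels, origin top-left, y increasing
downward, sub-pixel values allowed (detector outputs are continuous).

A detection line is a finite *directed* segment: the hive ("in") side
is the positive side of the cross product (q − p) × (x − p). The
`build_single_line` / `build_box` constructors fix this orientation, so
the order in which a user states the entrance endpoints cannot flip
in/out. The hive itself is taken to lie on the side of the entrance
segment nearer the image border — entrance cameras look at the entrance
from inside the arena, so the hive occupies the thin margin behind it.

A crossing by the movement M→N of a track center requires (a) M and N
on opposite sides of the line and (b) the segment MN to intersect the
*finite* detection segment. Requirement (b) matters: the line is
exactly as wide as the entrance, and movement beyond its endpoints must
not count. The direction is read off the side N lands on (hive side →
IN). This is equivalent in sign to the angle between MN and PQ
(`atan2(PQ × MN, PQ · MN)`), which the test suite verifies on 10,000
random configurations, but avoids angle wrap-around.

Degenerate-input conventions:

* a point exactly on the line counts as the *outside*; a bee that rests
  on the line therefore produces exactly one event when it finally
  crosses, never two;
* if one displacement crosses two box edges (e.g. straight through the
  box in one step), the edges are processed in the fixed order top,
  bottom, left, right and both crossings are applied sequentially;
* zero-length entrance segments, zero-area boxes and lines placed
  outside the image raise errors at construction.

The box's bottom line sits `bottom_margin_px` behind the entrance
(default 0 px, i.e. on the entrance segment itself); the exact offset
is not critical because bees vanish into the entrance before crossing
behind it, and it is exposed for cameras where the entrance lip is
visible.

## SORT tracker

The Kalman state is the standard SORT 7-vector (cx, cy, s, r, vx, vy,
vs) with constant aspect ratio r; process/measurement covariances
follow the reference implementation (measurement noise diag(1, 1, 10,
10); initial covariance diag(10, 10, 10, 10, 1e4, 1e4, 1e4); process
noise diag(1, 1, 1, 1, .01, .01, 1e-4)). A predicted area that would go
negative zeroes the area velocity.

Association maximizes total IoU over one-to-one matches; pairs under
`iou_min` contribute exactly zero gain to the assignment objective and
are discarded afterward, which makes the gated matching globally
optimal (a large-penalty mask is *not* equivalent: it prefers fewer
gated pairs over a better admissible matching; the test suite checks
optimality against exhaustive permutation enumeration).

Track lifecycle: unmatched detections spawn tracks; a track only emits
observations while matched on `min_hits` consecutive frames, with no
retroactive backfill — the simplest deterministic contract, at the cost
of losing each track's first `min_hits − 1` frames; tracks unmatched
longer than `max_age` frames are terminated and their identities are
never reused. Defaults `iou_min = 0.3`, `max_age = 1`, `min_hits = 3`
are the conventional SORT settings and are exposed as flags.

The validation suites run the tracker at `min_hits = 1` and
`iou_min = 0.1`: with no backfill, any `min_hits > 1` makes perfect
MOTA unattainable by construction, and a 0.3 gate is marginal for
near-vertical approach flight where the inter-frame displacement is a
large fraction of the (body length)/2 box height.

## Counting methods

Both counters consume identity-labeled boxes and use only the box
centers of two consecutive *observed* frames per identity — gaps from
missed detections are bridged by keeping the last observed center —
which is what makes crossing-based counting comparatively robust to
identity switches: an exchanged identity corrupts at most the one
transition spanning the switch.

Single-line method: every IN crossing increments the in-count, every
OUT crossing the out-count. Its two known error modes are (a) a bee
that dips across the line and returns is counted once in each
direction, and (b) bees entering or leaving below/beside the line are
missed entirely.

Box method: four lines around the entrance, every edge oriented with
the box interior positive. An inward crossing increments the in-count
and records the identity in the Already-counted queue (order-preserving,
no duplicates). An outward crossing by an identity *in* the queue
retracts: the identity is removed and the in-count decremented, and the
out-count is left untouched — the event log records this as a
correction. An outward crossing by an unknown identity (a bee that
emerged from the hive inside the box) counts as outgoing. The
retraction must also suppress the out-increment: if it did not, a
pass-through bee would still leave a spurious outgoing count and the
error would not be fixed. `purge_after` (default: never) drops
identities unseen for that many frames from the queue, guarding against
upstream identity reuse.

The event log is complete: replaying it (`replay_events`) reproduces
the totals exactly, and `net_events` applies corrections for
event-level evaluation.

## Evaluation metrics

CLEAR-MOT follows the standard accumulation: per frame, correspondences
from the previous frame are kept while their IoU clears the threshold
(default 0.5), remaining boxes are matched by Hungarian assignment
maximizing IoU, and an identity switch is charged whenever a matched
ground-truth object carries a different predicted identity than at its
previous match, including across occlusion gaps. MOTA can be negative;
empty ground truth is an error, not a score.

Identity metrics solve the optimal bijection between ground-truth and
predicted trajectories (square assignment problem with dummy
rows/columns) minimizing IDFP + IDFN, where a pair's matched frames
require box IoU at or above the same threshold. The implementation is
tested against brute-force enumeration of all bijections on small
scenes.

Counting evaluation matches predicted to ground-truth events
one-to-one, per direction, minimizing total frame distance subject to
|Δframe| ≤ tolerance (default 15 frames, ~0.6 s at 25 fps). The
published evaluations assigned TP/FP/FN by manual inspection; the time
tolerance is this package's operationalization for automated scoring.
Undefined ratios (no predictions, or no ground truth) are reported as
NaN rather than 0. Swapping the roles of ground truth and prediction
exactly swaps precision and recall.

Brightness uses ITU-R BT.601 luma (0.299 R + 0.587 G + 0.114 B) — the
common video convention — averaged over all pixels of an 8-bit frame.

## Synthetic scenes

The simulator emulates the behavior classes seen at an entrance:

* **incoming** — spawns far from the entrance (≥ 6 body lengths),
  flies via 1–2 waypoints, and terminates ~2 px in front of a random
  point on the entrance segment (inside the counting box, never behind
  the entrance);
* **outgoing** — the reverse;
* **pass-through** — a smooth lateral swoop whose depth profile is a
  Gaussian dip reaching `pass_depth_frac` (default 0.5) of the line
  offset: it crosses the line/top edge down and back without touching
  the entrance;
* **crawler below the line** — enters the strip between entrance and
  line laterally (exercising the finite-segment semantics and the box's
  side edges), wanders with tangential-only jitter so it can never
  cross the line, and leaves laterally.

Default geometry: 640×480 image, 80 px entrance near the bottom
border, body length 30 px, boxes body_length × body_length/2 (a 2:1
bee-like aspect), 25 frames/s, 400-frame scenes with 5 incoming and 5
outgoing bees.

Motion: constant speed per trajectory drawn from N(4.5, 1.0) px/frame
and capped at a quarter body length per frame, with per-frame Gaussian
jitter (σ = 0.8 px). The cap is a physical-consistency constraint, not
a tuning knob: any frame-to-frame overlap tracker presumes consecutive
boxes of a body-sized object intersect, so a camera whose pipeline
works at all bounds apparent per-frame displacement well below the box
size. In-flight waypoints stay above the detection line and laterally
over the entrance, making default approaches frontal; lateral/side
entries are exercised explicitly by the crawler class and by dedicated
fixtures rather than by default flights.

Corruption models detector and tracker failure modes separately:
detection-level localization noise (Gaussian on box position), missed
detections (Bernoulli per observation), false positives (Poisson per
frame, uniform in the arena), and track-level identity switches
(Bernoulli per track per frame, relabeling the remainder of the track
with a fresh identity) applied to the *true* tracks so counting
robustness can be studied independently of the tracker.

Every trajectory draws from its own counter-keyed substream of the
scenario seed (`default_rng([seed, k])`), so identical configurations
are bit-for-bit reproducible and adding a trajectory does not perturb
the others. `serialized=True` makes trajectories take turns in time —
the well-separated regime used by the exact-recovery validations.
Long-horizon scenes with a circadian profile can be composed
hour-by-hour using `diurnal_rates` (cosine bump over 06–18 h, peak at
noon, base rate at night) to draw per-hour Poisson counts.

What passing on synthetic scenes does *not* show: real detector error
is structured (motion blur, occlusion at the entrance hole, lighting),
bees interact and cluster at the entrance, and appearance is uniform —
so real-video scores will be lower than synthetic ones; the synthetic
results validate the algorithms' logic, not field performance.

## Numerical and interface choices

* Frames are 1-based; hour bins are half-open [h, h+1) with frame f
  mapped to time f / frame_rate.
* MOT text I/O is the 10-field comma-separated dialect; ground-truth
  files using field 7 as validity and fields 8–9 as class/visibility
  (or 9-field files) are accepted and normalized; boxes are written
  with 2 decimals, so write∘read is byte-stable.
* Geometry predicates use exact sign tests on cross products; no
  epsilon. Property tests exclude configurations within floating-point
  rounding distance of degeneracy, where the outcome is a tie-break.
* The tracker emits boxes from the Kalman posterior (not the raw
  matched detection); with clean detections the two agree closely.

## Known limitations

Appearance-based trackers (and hence re-identification after long
occlusion) are out of scope; identity switches between visually
identical bees are mitigated only by the counting method's
two-frame locality. The box method's retraction assumes upstream
identities are not reused for different animals within a scene —
`purge_after` is the safeguard. The simulator does not render images;
only the brightness utility touches pixel data.
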