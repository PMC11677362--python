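"""Published benchmark precision/recall/F1 values for the counting methods.

These are the printed per-direction counting scores (percent) of the
single-line and box methods under three trackers, and of both methods
across detection-line offsets (in bee body lengths).  They serve as
reference inputs for closed-form F1 reproduction: every F1 here should
be the harmonic mean of its own precision and recall.

One published cell is arithmetically inconsistent with its own
precision/recall pair (single-line, Deep OC-SORT, outgoing: printed
63.27 where the harmonic mean of 62.00 and 65.58 is 63.74); it is
flagged with ``consistent=False``.
"""

from __future__ import annotations

from typing import NamedTuple


class PrfTriple(NamedTuple):
    label: str
    direction: str  # "in" or "out"
    precision: float  # percent
    recall: float  # percent
    f1: float  # percent, as published
    consistent: bool = True  # published F1 agrees with Eq-(6) arithmetic


COUNTING_BENCHMARKS: list[PrfTriple] = [
    # single-line method, per tracker
    PrfTriple("single_line_bytetrack", "in", 65.03, 71.54, 68.13),
    PrfTriple("single_line_bytetrack", "out", 78.64, 72.08, 75.21),
    PrfTriple("single_line_ocsort", "in", 69.15, 79.07, 73.78),
    PrfTriple("single_line_ocsort", "out", 78.48, 70.72, 74.40),
    PrfTriple("single_line_deep_ocsort", "in", 49.09, 72.31, 58.48),
    PrfTriple("single_line_deep_ocsort", "out", 62.00, 65.58, 63.27, False),
    # box method, per tracker
    PrfTriple("box_bytetrack", "in", 83.64, 88.46, 85.98),
    PrfTriple("box_bytetrack", "out", 84.49, 87.34, 85.89),
    PrfTriple("box_ocsort", "in", 94.29, 88.85, 91.49),
    PrfTriple("box_ocsort", "out", 92.73, 85.71, 89.08),
    PrfTriple("box_deep_ocsort", "in", 80.43, 86.92, 83.55),
    PrfTriple("box_deep_ocsort", "out", 74.55, 85.77, 79.77),
    # single-line method at different line offsets (body lengths)
    PrfTriple("line_distance_near0", "in", 93.55, 58.00, 71.61),
    PrfTriple("line_distance_quarter", "in", 75.51, 74.00, 74.75),
    PrfTriple("line_distance_quarter", "out", 82.02, 73.74, 77.66),
    PrfTriple("line_distance_half", "in", 76.72, 89.00, 82.41),
    PrfTriple("line_distance_half", "out", 84.52, 71.72, 77.60),
    PrfTriple("line_distance_one", "in", 67.53, 52.00, 58.76),
    PrfTriple("line_distance_one", "out", 81.08, 60.61, 69.37),
    PrfTriple("line_distance_two", "in", 63.33, 38.00, 47.50),
    PrfTriple("line_distance_two", "out", 63.33, 19.20, 29.47),
    # box method at different top-line offsets (body lengths)
    PrfTriple("box_distance_quarter", "in", 91.59, 98.00, 94.69),
    PrfTriple("box_distance_quarter", "out", 93.07, 94.95, 94.00),
    PrfTriple("box_distance_half", "in", 96.03, 97.00, 96.51),
    PrfTriple("box_distance_half", "out", 90.38, 95.95, 93.08),
    PrfTriple("box_distance_one", "in", 73.50, 86.00, 79.26),
    PrfTriple("box_distance_one", "out", 78.43, 80.81, 79.60),
    PrfTriple("box_distance_two", "in", 48.70, 56.00, 52.10),
    PrfTriple("box_distance_two", "out", 48.84, 42.42, 45.40),
]
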