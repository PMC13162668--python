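"""Zone-occupancy behavior inference.

The detector emits only two postures, lying and standing.  Eating and
drinking are recovered geometrically: the pen's feeder and drinker are
delimited as axis-aligned pixel rectangles, and a standing animal whose
bounding box occupies enough of such a region of interest is inferred to be
using it.  Occupancy of a zone follows

    OC = area( union of (detection box ∩ zone) ) / area(zone)

and a zone counts as "in use" when OC >= 0.5 (configurable).  Feeder zones
are only considered during scheduled feeding windows — outside them pigs
explore an empty trough, which must not count as eating — while drinking can
occur at any time.  An ``inactive_feeder`` zone (an unused trough that
attracts both pigs and detector false positives) never produces eating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from shapely.geometry import box as _shapely_box
from shapely.ops import unary_union

from .detections import Detection, FrameDetections, PixelBox, VideoMeta, intersection_area

__all__ = [
    "BEHAVIORS",
    "Zone",
    "FeedingSchedule",
    "FrameActivity",
    "zone_occupancy",
    "classify_frame",
    "infer_video",
    "zones_from_frame",
    "activity_frame",
]

#: the four-class ethogram, in reporting order
BEHAVIORS: tuple[str, ...] = ("lying", "standing", "eating", "drinking")

ZoneRole = Literal["feeder", "drinker", "inactive_feeder"]
_ROLE_BEHAVIOR = {"feeder": "eating", "drinker": "drinking"}


@dataclass(frozen=True)
class Zone:
    """A named feeder/drinker rectangle in pixel coordinates."""

    zone_id: str
    role: ZoneRole
    rect: PixelBox

    def __post_init__(self) -> None:
        if self.role not in ("feeder", "drinker", "inactive_feeder"):
            raise ValueError(f"unknown zone role {self.role!r}")
        if self.rect.area <= 0:
            raise ValueError(f"zone {self.zone_id!r} has a degenerate rectangle")


def zones_from_frame(df: pd.DataFrame) -> list[Zone]:
    """Build :class:`Zone` objects from a zones CSV DataFrame."""
    return [
        Zone(str(r.zone_id), str(r.role), PixelBox(int(r.x0), int(r.y0), int(r.x1), int(r.y1)))
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class FeedingSchedule:
    """Daily feed-distribution windows as ``(start, end)`` seconds-of-day,
    half-open.  The default emulates twice-daily feeding."""

    windows: tuple[tuple[float, float], ...] = (
        (7 * 3600.0, 9 * 3600.0),
        (15 * 3600.0, 17 * 3600.0),
    )

    def __post_init__(self) -> None:
        spans = sorted(self.windows)
        for start, end in spans:
            if not 0 <= start < end <= 86400:
                raise ValueError(f"feeding window ({start}, {end}) invalid")
        for (_, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("feeding windows must not overlap")

    def in_window(self, seconds_of_day: float) -> bool:
        t = seconds_of_day % 86400.0
        return any(start <= t < end for start, end in self.windows)

    @property
    def total_seconds(self) -> float:
        return sum(end - start for start, end in self.windows)

    @classmethod
    def empty(cls) -> "FeedingSchedule":
        return cls(windows=())


@dataclass(frozen=True)
class FrameActivity:
    """Behavior assignment of every retained detection in one frame."""

    frame_index: int
    counts: dict[str, int]
    assignments: tuple[str, ...]  # behavior per detection, same order as input

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != len(self.assignments):
            raise ValueError("counts must sum to the number of assigned detections")


def zone_occupancy(detections: Sequence[PixelBox], zone: Zone) -> float:
    """Occupancy OC of a zone: union-of-intersections area over zone area.

    Duplicate or overlapping boxes are not double counted (union semantics),
    so OC is in [0, 1] and monotone under adding detections.
    """
    if zone.rect.area == 0:
        raise ValueError("zone has zero area")
    pieces = []
    zx0, zy0, zx1, zy1 = zone.rect
    for b in detections:
        if intersection_area(b, zone.rect) > 0:
            pieces.append(
                _shapely_box(max(b.x0, zx0), max(b.y0, zy0), min(b.x1, zx1), min(b.y1, zy1))
            )
    if not pieces:
        return 0.0
    return unary_union(pieces).area / zone.rect.area


def classify_frame(
    frame: FrameDetections,
    zones: Sequence[Zone],
    schedule: FeedingSchedule,
    meta: VideoMeta,
    seconds_of_day: float | None = None,
    occupancy_threshold: float = 0.5,
    occupancy_rule: Literal["zone", "box"] = "zone",
) -> FrameActivity:
    """Assign one behavior to each detection of a frame.

    Lying detections are always lying.  A standing detection becomes eating
    (active feeder, inside a feeding window) or drinking (drinker, any time)
    when the occupancy rule holds; otherwise it stays standing.

    occupancy_rule="zone" (default, the published convention): a zone is in
    use when the union occupancy OC of all standing boxes reaches
    ``occupancy_threshold``; every standing box intersecting an in-use zone
    is assigned that zone's behavior.
    occupancy_rule="box": per detection, intersection / box area must reach
    the threshold.

    A detection qualifying for several zones goes to the one with the larger
    per-detection intersection fraction; ties favor the drinker (drinking
    bouts are rare and short, so losing one costs more).

    ``seconds_of_day`` anchors the frame on the feeding-schedule clock; it
    defaults to the frame timestamp (video starting at midnight).
    """
    if seconds_of_day is None:
        seconds_of_day = frame.timestamp
    pixel_boxes = [d.box.to_pixels(meta) for d in frame.detections]
    standing_boxes = [
        b for d, b in zip(frame.detections, pixel_boxes) if d.class_label == "standing"
    ]

    candidate_zones: list[Zone] = []
    for zone in zones:
        if zone.role == "inactive_feeder":
            continue
        if zone.role == "feeder" and not schedule.in_window(seconds_of_day):
            continue
        candidate_zones.append(zone)

    active: dict[str, bool] = {}
    if occupancy_rule == "zone":
        for zone in candidate_zones:
            active[zone.zone_id] = (
                zone_occupancy(standing_boxes, zone) >= occupancy_threshold
            )

    assignments: list[str] = []
    for det, pbox in zip(frame.detections, pixel_boxes):
        if det.class_label == "lying":
            assignments.append("lying")
            continue
        if det.class_label != "standing":
            # unknown detector classes contribute to no ethogram behavior
            assignments.append(det.class_label)
            continue
        best: tuple[float, int, str] | None = None  # (frac, drinker-priority, behavior)
        for zone in candidate_zones:
            inter = intersection_area(pbox, zone.rect)
            if inter == 0:
                continue
            if occupancy_rule == "zone":
                if not active[zone.zone_id]:
                    continue
                frac = inter / zone.rect.area
            else:
                frac = inter / pbox.area
                if frac < occupancy_threshold:
                    continue
            key = (frac, 1 if zone.role == "drinker" else 0, _ROLE_BEHAVIOR[zone.role])
            if best is None or key[:2] > best[:2]:
                best = key
        assignments.append(best[2] if best is not None else "standing")

    counts = {b: 0 for b in BEHAVIORS}
    for a in assignments:
        counts[a] = counts.get(a, 0) + 1
    return FrameActivity(frame.frame_index, counts, tuple(assignments))


def infer_video(
    frames: Iterable[FrameDetections],
    zones: Sequence[Zone],
    schedule: FeedingSchedule,
    meta: VideoMeta,
    video_start_seconds_of_day: float = 0.0,
    occupancy_threshold: float = 0.5,
    occupancy_rule: Literal["zone", "box"] = "zone",
) -> tuple[list[FrameActivity], dict[str, int]]:
    """Classify every frame of a video and accumulate per-behavior frame
    counts.

    Frames must be ordered with unique indices; a frame timestamp outside the
    video span (when ``meta.n_frames`` is known) is an error.  Deterministic:
    totals equal the sum over frames.
    """
    activities: list[FrameActivity] = []
    totals = {b: 0 for b in BEHAVIORS}
    seen: set[int] = set()
    span = None if meta.n_frames is None else meta.n_frames / meta.native_fps
    for frame in frames:
        if frame.frame_index in seen:
            raise ValueError(f"duplicated frame_index {frame.frame_index}")
        seen.add(frame.frame_index)
        if span is not None and not 0.0 <= frame.timestamp <= span:
            raise ValueError(
                f"frame {frame.frame_index} timestamp {frame.timestamp:.3f}s "
                f"outside video span [0, {span:.3f}]s"
            )
        activity = classify_frame(
            frame,
            zones,
            schedule,
            meta,
            seconds_of_day=video_start_seconds_of_day + frame.timestamp,
            occupancy_threshold=occupancy_threshold,
            occupancy_rule=occupancy_rule,
        )
        activities.append(activity)
        for b, c in activity.counts.items():
            totals[b] = totals.get(b, 0) + c
    return activities, totals


def activity_frame(activities: Sequence[FrameActivity], meta: VideoMeta) -> pd.DataFrame:
    """Tabulate per-frame activity counts:
    ``frame_index,timestamp,lying,standing,eating,drinking``."""
    rows = []
    for a in activities:
        row = {"frame_index": a.frame_index, "timestamp": a.frame_index / meta.native_fps}
        for b in BEHAVIORS:
            row[b] = a.counts.get(b, 0)
        rows.append(row)
    return pd.DataFrame(rows)
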