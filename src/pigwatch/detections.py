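"""YOLO-format label I/O and box geometry primitives.

A label file carries one line per detected object::

    class_id cx cy w h [confidence]

where ``(cx, cy)`` is the box center and ``(w, h)`` its size, all normalized
to the image dimensions (fractions in [0, 1]).  Ground-truth files omit the
confidence column.  Pixel coordinates use the standard image convention:
origin top-left, x right, y down, half-open integer ranges
``[x0, x1) × [y0, y1)``; denormalization rounds to the nearest integer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "LabelParseError",
    "LabelWarning",
    "VideoMeta",
    "NormalizedBox",
    "PixelBox",
    "Detection",
    "FrameDetections",
    "TWO_CLASS_NAMES",
    "FOUR_CLASS_NAMES",
    "parse_label_line",
    "parse_label_text",
    "parse_label_file",
    "write_label_lines",
    "write_label_file",
    "filter_confidence",
    "intersection_area",
    "iou",
    "read_zones_csv",
    "write_zones_csv",
]


class LabelParseError(ValueError):
    """A malformed label line; carries the 1-based line number."""


class LabelWarning(UserWarning):
    """Recoverable label oddities: unknown class ids, clipped boxes."""


#: detector output scheme: eating/drinking are merged into standing upstream
TWO_CLASS_NAMES: Mapping[int, str] = {0: "lying", 1: "standing"}
#: ground-truth annotation scheme with the full ethogram
FOUR_CLASS_NAMES: Mapping[int, str] = {0: "lying", 1: "standing", 2: "eating", 3: "drinking"}


@dataclass(frozen=True)
class VideoMeta:
    """Frame geometry and rate of one recording (defaults: 640×360 @ 25 fps)."""

    width: int = 640
    height: int = 360
    native_fps: float = 25.0
    n_frames: int | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.native_fps <= 0:
            raise ValueError("video dimensions and fps must be positive")
        if self.n_frames is not None and self.n_frames <= 0:
            raise ValueError("n_frames must be positive when given")


class PixelBox(NamedTuple):
    """Axis-aligned pixel rectangle, half-open: [x0, x1) × [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def area(self) -> int:
        return max(0, self.x1 - self.x0) * max(0, self.y1 - self.y0)

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def clip(self, meta: VideoMeta) -> "PixelBox":
        return PixelBox(
            max(0, self.x0), max(0, self.y0), min(meta.width, self.x1), min(meta.height, self.y1)
        )


@dataclass(frozen=True)
class NormalizedBox:
    """Center-format normalized box: cx, cy in [0,1]; w, h in (0,1]."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box center ({self.cx}, {self.cy}) outside [0,1]")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box size ({self.w}, {self.h}) outside (0,1]")

    def to_pixels(self, meta: VideoMeta, clip: bool = True) -> PixelBox:
        """Denormalize to a pixel rectangle, rounding edges to the nearest
        integer and (by default) clipping to the image with a warning."""
        x0 = round((self.cx - self.w / 2.0) * meta.width)
        y0 = round((self.cy - self.h / 2.0) * meta.height)
        x1 = round((self.cx + self.w / 2.0) * meta.width)
        y1 = round((self.cy + self.h / 2.0) * meta.height)
        box = PixelBox(x0, y0, x1, y1)
        if clip:
            clipped = box.clip(meta)
            if clipped != box:
                warnings.warn(
                    f"box {box} extends past {meta.width}x{meta.height} image; clipped",
                    LabelWarning,
                    stacklevel=2,
                )
            if clipped.area == 0:
                raise ValueError(f"box {box} is empty after clipping to the image")
            return clipped
        return box

    @classmethod
    def from_pixels(cls, box: PixelBox, meta: VideoMeta) -> "NormalizedBox":
        return cls(
            cx=(box.x0 + box.x1) / (2.0 * meta.width),
            cy=(box.y0 + box.y1) / (2.0 * meta.height),
            w=(box.x1 - box.x0) / meta.width,
            h=(box.y1 - box.y0) / meta.height,
        )


@dataclass(frozen=True)
class Detection:
    """One class-labeled box, optionally confidence-scored (ground truth has
    no confidence)."""

    class_label: str
    box: NormalizedBox
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0,1]")


@dataclass(frozen=True)
class FrameDetections:
    """All detections of one frame."""

    frame_index: int
    timestamp: float  # seconds from video start
    detections: tuple[Detection, ...]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be nonnegative")


def parse_label_line(
    text: str,
    line_number: int = 1,
    class_names: Mapping[int, str] = TWO_CLASS_NAMES,
) -> Detection:
    """Parse one YOLO label line (5 fields, or 6 with confidence).

    Unknown class ids are preserved as ``"class_<id>"`` with a
    :class:`LabelWarning`; malformed lines raise :class:`LabelParseError`
    carrying the line number.
    """
    fields = text.split()
    if len(fields) not in (5, 6):
        raise LabelParseError(
            f"line {line_number}: expected 5 or 6 fields, got {len(fields)}: {text!r}"
        )
    try:
        class_id = int(fields[0])
        nums = [float(f) for f in fields[1:]]
    except ValueError as exc:
        raise LabelParseError(f"line {line_number}: non-numeric field in {text!r}") from exc
    try:
        box = NormalizedBox(*nums[:4])
    except ValueError as exc:
        raise LabelParseError(f"line {line_number}: {exc}") from exc
    confidence = nums[4] if len(nums) == 5 else None
    if confidence is not None and not 0.0 <= confidence <= 1.0:
        raise LabelParseError(f"line {line_number}: confidence {confidence} outside [0,1]")
    if class_id in class_names:
        label = class_names[class_id]
    else:
        label = f"class_{class_id}"
        warnings.warn(
            f"line {line_number}: unknown class id {class_id}; kept as {label!r}",
            LabelWarning,
            stacklevel=2,
        )
    return Detection(class_label=label, box=box, confidence=confidence)


def parse_label_text(
    text: str,
    frame_index: int,
    meta: VideoMeta,
    class_names: Mapping[int, str] = TWO_CLASS_NAMES,
) -> FrameDetections:
    """Parse one frame's label file content; timestamp derives from the
    frame index and native fps."""
    dets = tuple(
        parse_label_line(line, i + 1, class_names)
        for i, line in enumerate(text.splitlines())
        if line.strip()
    )
    return FrameDetections(
        frame_index=frame_index,
        timestamp=frame_index / meta.native_fps,
        detections=dets,
    )


def parse_label_file(
    path: str | Path,
    meta: VideoMeta,
    class_names: Mapping[int, str] = TWO_CLASS_NAMES,
    frame_index: int | None = None,
) -> FrameDetections:
    """Parse ``<frame_index>.txt``; the index defaults to the file stem."""
    path = Path(path)
    if frame_index is None:
        try:
            frame_index = int(path.stem)
        except ValueError:
            raise LabelParseError(
                f"{path}: cannot infer frame index from file name; pass frame_index"
            ) from None
    try:
        return parse_label_text(path.read_text(), frame_index, meta, class_names)
    except LabelParseError as exc:
        raise LabelParseError(f"{path}: {exc}") from None


def write_label_lines(
    detections: Sequence[Detection],
    class_names: Mapping[int, str] = TWO_CLASS_NAMES,
) -> str:
    """Serialize detections to YOLO label text, 6-decimal fixed point.

    Inverse of parsing up to the 1e-6 rounding of coordinates.
    """
    by_name = {name: cid for cid, name in class_names.items()}
    lines = []
    for det in detections:
        try:
            cid = by_name[det.class_label]
        except KeyError:
            if det.class_label.startswith("class_"):
                cid = int(det.class_label.removeprefix("class_"))
            else:
                raise ValueError(f"class {det.class_label!r} not in the configured scheme")
        b = det.box
        parts = [str(cid)] + [f"{v:.6f}" for v in (b.cx, b.cy, b.w, b.h)]
        if det.confidence is not None:
            parts.append(f"{det.confidence:.6f}")
        lines.append(" ".join(parts))
    return "\n".join(lines) + ("\n" if lines else "")


def write_label_file(
    frame: FrameDetections,
    directory: str | Path,
    class_names: Mapping[int, str] = TWO_CLASS_NAMES,
) -> Path:
    """Write one frame's labels as ``<directory>/<frame_index>.txt``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{frame.frame_index}.txt"
    path.write_text(write_label_lines(frame.detections, class_names))
    return path


def filter_confidence(
    detections: Iterable[Detection], threshold: float = 0.70
) -> tuple[Detection, ...]:
    """Drop detections with confidence strictly below ``threshold``.

    The boundary is inclusive (kept iff confidence >= threshold); ground-truth
    boxes without confidence always pass.  Order is preserved and the filter
    is idempotent.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"confidence threshold {threshold} outside [0,1]")
    return tuple(
        d for d in detections if d.confidence is None or d.confidence >= threshold
    )


def intersection_area(a: PixelBox, b: PixelBox) -> int:
    """Overlap area (px²) of two pixel rectangles; 0 when disjoint."""
    w = min(a.x1, b.x1) - max(a.x0, b.x0)
    h = min(a.y1, b.y1) - max(a.y0, b.y0)
    return max(0, w) * max(0, h)


def iou(a: PixelBox, b: PixelBox) -> float:
    """Intersection over union of two pixel rectangles, in [0, 1]."""
    if a.area == 0 or b.area == 0:
        raise ValueError("IoU of a degenerate box is undefined")
    inter = intersection_area(a, b)
    return inter / (a.area + b.area - inter)


def read_zones_csv(path: str | Path) -> pd.DataFrame:
    """Read the pen-geometry CSV ``zone_id,role,x0,y0,x1,y1`` (pixels)."""
    df = pd.read_csv(path)
    missing = {"zone_id", "role", "x0", "y0", "x1", "y1"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_zones_csv(zones: Iterable, path: str | Path) -> None:
    """Write zones (objects with zone_id, role, rect) to CSV."""
    rows = [
        {
            "zone_id": z.zone_id,
            "role": z.role,
            "x0": z.rect.x0,
            "y0": z.rect.y0,
            "x1": z.rect.x1,
            "y1": z.rect.y1,
        }
        for z in zones
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
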